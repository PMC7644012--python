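# Membership sets under which the documented worked example
# (ratio 1.45, weight 72 g -> truth value 0.449, single yolk) evaluates.
gi: {low: 1.30, medium: 1.40, high: 1.50}
wi: {low: 66.0, medium: 74.0, high: 82.0}
decision_threshold: 0.5
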