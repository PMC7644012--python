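# Production membership-function preset: low single-yolk error.
gi: {low: 1.30, medium: 1.40, high: 1.50}
wi: {low: 65.0, medium: 75.0, high: 85.0}
decision_threshold: 0.5
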