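{"omega": 0.8, "F": 0.025, "h": 0.025, "q0": 1e-4, "qk": 0.1, "max_generations": 100000}
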