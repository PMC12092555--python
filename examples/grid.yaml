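# Example simulation grid: a few cells of the factorial design.
# nu: inf -> normal data; finite nu -> Student-t noise (SD-standardized).
- {delta: 0.0, sdr: 1.0, nu: inf, total_n: 20, allocation: 1.0, reps: 10}
- {delta: 0.5, sdr: 2.0, nu: inf, total_n: 50, allocation: 1.0, reps: 10}
- {delta: 0.5, sdr: 2.0, nu: 5, total_n: 100, allocation: 2.0, reps: 10}
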