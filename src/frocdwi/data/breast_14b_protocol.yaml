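# 14-b-value breast DWI protocol: nominal b-values (s/mm^2) with the number
# of averaged acquisitions per b, and the monopolar diffusion gradient timings.
b_values: [0, 50, 80, 100, 150, 200, 400, 600, 800, 1000, 1500, 2000, 2500, 3000]
n_averages: [1, 1, 1, 1, 1, 1, 1, 1, 1, 2, 2, 2, 3, 3]
delta: 25.66    # gradient pulse width, ms
big_delta: 30.13  # gradient interval, ms
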