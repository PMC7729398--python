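"""Pre-model reductions: Po,max from ensemble noise, i_s from histograms.

The maximal open probability follows from the current variance at the
peak (sigma^2 = i * I_max * (1 - Po) for a binomial channel ensemble);
the unitary current comes from a two-Gaussian amplitude-histogram fit.
"""

from p2xkin import gaussian_histogram_fit, po_max_from_noise
from p2xkin.synthetic import generate_noise_sweeps, generate_single_channel_samples

sweeps = generate_noise_sweeps(L_saturating=100.0, n_sweeps=100, seed=5)
noise = po_max_from_noise(sweeps.sigma2_peak, sweeps.sigma2_baseline,
                          sweeps.i, sweeps.i_max)
print(f"peak variance          : {sweeps.sigma2_peak:8.1f} pA^2")
print(f"peak current           : {sweeps.i_max:8.1f} pA")
print(f"Po,max from noise      : {noise.po_max:.3f}  (generating {sweeps.true_po:.3f})")

samples = generate_single_channel_samples(i_s=0.80, sigma=0.15, n=10_000, seed=5)
amp = gaussian_histogram_fit(samples)
print(f"single-channel current : {amp.i_s:.3f} pA  (generating 0.80 pA)")
# Both reductions close the loop: the values the generator used are
# recovered from the synthetic recordings alone.
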