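"""Flickering: events below the filter length need local tests + deconvolution.

A 3-sample (60 us) blockage peak is far shorter than the filter length
(m = 11 samples).  The above-filter-length detector alone misses it; the
two-stage detector (multiscale stage at alpha1 + filter-aware local tests at
alpha2) resolves it, and pair deconvolution recovers the true amplitude that
the filtered data never reach."""

import numpy as np

import ionideal as ii

filt = ii.make_filter(4, 0.1, 5e4)
fs = filt.sample_rate
n = 2048

t1, t2 = 900 / fs, 903 / fs  # 3-sample peak
truth = ii.StepSignal(change_times=[t1, t2], levels=[0.0, 0.65, 0.0], end=n / fs)
trace = ii.simulate_trace(truth, filt, n, sigma=0.1,
                          seed=np.random.default_rng([5, 9]))

store = ii.CritvalStore()
stage1 = ii.jsmurf(
    trace, filt, ii.MethodConfig(method="jsmurf", alpha=0.01, r=300, seed=13), store
)
print(f"multiscale stage alone: {stage1.fit.n_changes} changes (peak missed)")

config = ii.MethodConfig(method="hilde", alpha1=0.01, alpha2=0.04, r=300,
                         seed=13, l_max=10)
fit = ii.hilde_detect(trace, filt, config, store)
print(f"with local short-event tests: {fit.fit.n_changes} changes")

ideal = ii.local_deconvolution(trace, filt, fit)
amp = ideal.levels[1] - (ideal.levels[0] + ideal.levels[2]) / 2
print(f"deconvolved peak: [{ideal.change_times[0]*fs:.2f}, "
      f"{ideal.change_times[1]*fs:.2f}] samples (true [900, 903])")
print(f"deconvolved amplitude: {amp:.3f} nS (true 0.65)")
print(
    "\nThe filtered peak only reaches ~0.4 nS in the data; the local test "
    "corrects for the kernel attenuation and deconvolution restores the "
    "time-continuous change times and the full amplitude."
)
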