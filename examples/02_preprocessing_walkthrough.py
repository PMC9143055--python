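"""Spectral preprocessing on small constructed inputs.

Shows each preprocessing primitive in isolation: SNR peak picking on a
profile-mode spectrum, common-axis construction from jittered runs, and
recovery of a run's global ppm calibration offset.
"""

import numpy as np

from msitma import MassAxis, PeakList, build_common_axis, detect_peaks, \
    estimate_ppm_offset, render_profile

rng = np.random.default_rng(0)

# --- peak picking: three peaks of very different heights on a noisy profile
true_mz = np.array([412.0, 500.0, 763.4])
heights = np.array([50.0, 20.0, 25.0])
axis = np.linspace(100.0, 1000.0, 18001)  # 50 mTh grid
profile = render_profile(PeakList(true_mz, heights, np.zeros(3)), axis,
                         width_mz=0.15, noise_sd=1.0, seed=1)
peaks = detect_peaks(axis, profile, snr_min=6.0)
print("detected centroids:", np.round(peaks.mz, 3))
print("true centroids:    ", true_mz)
print("-> every local maximum clearing the SNR threshold is kept (6x the")
print("   robust baseline noise here: on an 18,000-bin grid the tallest pure-")
print("   noise excursion reaches ~4.5 sigma, so 6 separates cleanly);")
print("   centroids are refined by the intensity-weighted mean over the")
print("   above-half-maximum bins, so they land within a bin of the truth.\n")

# --- common axis: two runs of the same panel, shifted +4 / -3 ppm
panel = np.sort(rng.uniform(100, 1000, 30))
run_a = PeakList(panel * (1 + 4e-6), np.ones(30), np.zeros(30))
run_b = PeakList(panel * (1 - 3e-6), np.ones(30), np.zeros(30))
common = build_common_axis([run_a, run_b], ppm_tol=10)
print(f"pooled {len(run_a) + len(run_b)} centroids -> {len(common)} common-axis entries")
print("-> centroids within 10 ppm merge into one shared entry per compound.\n")

# --- recalibration: each run's global offset relative to the common axis
for name, run in (("run A", run_a), ("run B", run_b)):
    off = estimate_ppm_offset(run, common, ppm_tol=10)
    print(f"{name}: estimated offset {off:+.2f} ppm")
print("-> the median matched-peak deviation recovers each run's mass-axis")
print("   shift (truth: +3.5 and -3.5 ppm relative to the merged axis),")
print("   which is subtracted before the runs are rasterised together.")
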