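"""Run one subject through the preprocessing chain to a Fisher-z connectome.

Chain: drop first 10 s -> nuisance regression (trend, motion, tissue means,
and their derivatives; 20 regressors) -> 0.008-0.1 Hz band-pass -> FD
scrubbing at 0.5 mm -> Pearson correlation -> Fisher r-to-z -> vectorized
strict lower triangle.
"""

import numpy as np

import lscpm

spec = lscpm.CohortSpec(
    n_subjects=1, n_rois=30, n_timepoints=400, tr_seconds=0.72,
    n_signal_edges=5, effect_size=1.0, motion_spike_rate=0.01, seed=7,
)
rec = lscpm.generate_timeseries_cohort(spec).subjects[0]

rec2 = lscpm.drop_initial(rec, seconds=10.0)
print(f"dropped {rec.n_timepoints - rec2.n_timepoints} initial frames "
      f"(10 s at TR={rec.tr_seconds} s)")

nuisance = lscpm.build_nuisance(rec2)
resid = lscpm.regress_nuisance(rec2.timeseries, nuisance)
print(f"nuisance model: {nuisance.shape[1]} regressors")

filtered = lscpm.bandpass(resid, rec2.tr_seconds)
fd = lscpm.framewise_displacement(rec2.motion)
censored, mask, _ = lscpm.scrub(filtered, fd)
print(f"scrubbed {int((~mask).sum())} frame(s) with FD > 0.5 mm; "
      f"{censored.shape[0]} retained")

conn = lscpm.connectivity(censored)
edges = lscpm.vectorize(conn)
print(f"connectome: {conn.n_rois}x{conn.n_rois}, vectorized to "
      f"{edges.shape[0]} edges (R(R-1)/2)")
print(f"Fisher-z range: [{edges.min():.2f}, {edges.max():.2f}]")
# For the study-scale atlas (R=427) the same chain yields 90,951 edges.
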