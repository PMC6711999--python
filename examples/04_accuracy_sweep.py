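"""Accuracy of coupling-strength recovery versus noise level (small-scale).

Runs the coupled-sinusoid simulation at several SNRs (8 replicates each -
the full study uses 50) and reports the mean relative error of the
calibrated time-frequency readout against the Hilbert baseline's
conventional normalized-MVL readout.  The time-frequency estimate stays
accurate into negative SNR; the baseline degrades much faster.
"""
import numpy as np

import tfpac as tp

res = tp.accuracy_snr_study(seed=0, n_reps=8, snr_values=(-5, 0, 5, 10))
table = res.table
print("SNR_dB  tf_rel_err%  hilbert_rel_err%")
for snr in (-5, 0, 5, 10):
    row = {est: table[(table["value"] == snr) & (table["estimator"] == est)]
           ["rel_error_mean"].iloc[0] for est in ("tf", "hilbert")}
    print(f"{snr:6d}  {row['tf']:11.1f}  {row['hilbert']:16.1f}")
print("\n(relative error = |detected - planted| / planted x 100%, "
      "averaged over replicates)")
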