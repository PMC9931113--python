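"""Transcribed covariance constants of the simulation study.

``S1`` is the 6 x 6 covariance block over the intercept and the five
piecewise-linear gradient-change coefficients used to draw 'true'
coefficients; ``SIGMA1`` is its diagonal counterpart used in the model
priors (same diagonal, zero elsewhere).  ``FOURIER_SCALE`` is the small
variance put on every Fourier coefficient so the seasonal component does
not dominate the trend.

Both matrices are checked symmetric positive-definite at import; a failed
check means a transcription error and is a hard failure.
"""

import numpy as np

S1 = np.array(
    [
        [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 4.0, -3.0, -1.0, 0.0, 0.0],
        [0.0, -3.0, 5.0, -4.0, 2.0, 0.0],
        [0.0, -1.0, -4.0, 10.0, -4.0, 0.0],
        [0.0, 0.0, 2.0, -4.0, 5.0, 2.0],
        [0.0, 0.0, 0.0, 0.0, 2.0, 6.0],
    ]
)

SIGMA1 = np.diag(np.diag(S1))

FOURIER_SCALE = 0.001

for _name, _mat in (("S1", S1), ("SIGMA1", SIGMA1)):
    if not np.array_equal(_mat, _mat.T):
        raise RuntimeError(f"{_name} transcription is not symmetric")
    try:
        np.linalg.cholesky(_mat)
    except np.linalg.LinAlgError as _exc:  # pragma: no cover
        raise RuntimeError(f"{_name} transcription is not positive-definite") from _exc
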