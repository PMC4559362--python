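"""Previously reported numbers used as frozen fixtures in tests.

``REFERENCE_LINEAR_MATRIX`` is a published 5x5 transformation matrix for
the linear surrogate: rows map to outputs in the order (FOXP3, IFNg_out,
IL17, RORgt, Tbet), columns to the augmented input (1, IFNg, IL12, IL6,
TGFb).  The two error rows are published per-output mean absolute test
errors (IL17, RORgt, IFNg_out, Tbet, FOXP3 order) used to exercise the
sum-of-error aggregation.
"""

import numpy as np

REFERENCE_LINEAR_MATRIX = np.array(
    [
        [0.0386, 0.531, 0.408, 0.387, 0.663],  # FOXP3
        [-0.0259, -0.0536, 0.155, 0.146, 0.0267],  # IFNg_out
        [-0.0303, 0.297, -0.0466, -0.0592, 0.129],  # IL17
        [-0.0191, -0.568, 0.773, 0.811, -0.302],  # RORgt
        [0.00558, 0.0551, -0.130, -0.132, -0.198],  # Tbet
    ]
)

#: Intercept column of the matrix above (prediction at the zero milieu).
REFERENCE_INTERCEPTS = REFERENCE_LINEAR_MATRIX[:, 0].copy()

#: Reported per-output MAE of the selected neural network (sum prints as 0.190).
NN_ERROR_ROW = (0.0561, 0.0419, 0.0407, 0.0142, 0.0368)

#: Reported per-output MAE of the selected random forest (sums to 0.2123).
RF_ERROR_ROW = (0.0261, 0.032, 0.0326, 0.0920, 0.0296)
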