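"""Independent oracles used to check the implementation by a second route.

The steady-state oracle solves the three coupled regulator equilibrium
equations by damped fixed-point iteration (never by integrating the ODEs),
then closes the two secretion readouts in closed form.  The gradient oracle
differentiates the MLP loss by central finite differences.
"""

import numpy as np

from tcellfate.kinetics import KineticParams, hill_activation, hill_inhibition
from tcellfate.surrogates import mlp_sse_and_gradients


def fixed_point_steady_state(
    milieu: np.ndarray,
    params: KineticParams | None = None,
    damping: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 200_000,
) -> np.ndarray:
    """Equilibrium readouts (IL17, RORgt, IFNg_out, Tbet, FOXP3 order)."""
    p = params or KineticParams()
    ifng, il12, il6, tgfb = milieu
    A = lambda x, k: hill_activation(x, k, p.n_hill)
    I = lambda x, k: hill_inhibition(x, k, p.n_hill)
    scale = p.v / p.delta
    tbet = rorgt = foxp3 = 0.0
    for _ in range(max_iter):
        new_tbet = scale * A(ifng + il12, p.k_act) * I(rorgt, p.k_inh) * I(foxp3, p.k_inh)
        new_rorgt = scale * A(tgfb, p.k_act) * A(il6, p.k_act) * I(tbet, p.k_inh) * I(foxp3, p.k_inh)
        new_foxp3 = scale * A(tgfb, p.k_act) * I(il6, p.k_act) * I(tbet, p.k_inh) * I(rorgt, p.k_inh)
        new_tbet = (1 - damping) * tbet + damping * new_tbet
        new_rorgt = (1 - damping) * rorgt + damping * new_rorgt
        new_foxp3 = (1 - damping) * foxp3 + damping * new_foxp3
        converged = (
            max(abs(new_tbet - tbet), abs(new_rorgt - rorgt), abs(new_foxp3 - foxp3)) < tol
        )
        tbet, rorgt, foxp3 = new_tbet, new_rorgt, new_foxp3
        if converged:
            break
    else:  # pragma: no cover
        raise RuntimeError("fixed-point oracle did not converge")
    il17 = scale * A(rorgt, p.k_sec)
    ifng_out = scale * A(tbet, p.k_sec)
    return np.array([il17, rorgt, ifng_out, tbet, foxp3])


def finite_difference_mlp_gradients(
    X: np.ndarray,
    Y: np.ndarray,
    params: dict[str, np.ndarray],
    h: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Central-difference gradients of the MLP loss for every weight array."""
    grads = {}
    for name, array in params.items():
        numeric = np.zeros_like(array)
        iterator = np.nditer(array, flags=["multi_index"])
        for _ in iterator:
            idx = iterator.multi_index
            orig = array[idx]
            array[idx] = orig + h
            plus, _ = mlp_sse_and_gradients(X, Y, **params)
            array[idx] = orig - h
            minus, _ = mlp_sse_and_gradients(X, Y, **params)
            array[idx] = orig
            numeric[idx] = (plus - minus) / (2 * h)
        grads[name] = numeric
    return grads


def gradient_discrepancy(analytic: dict, numeric: dict) -> float:
    """Worst norm-wise relative discrepancy over the weight arrays."""
    worst = 0.0
    for name in analytic:
        a, n = analytic[name], numeric[name]
        rel = np.linalg.norm(a - n) / max(np.linalg.norm(a), np.linalg.norm(n), 1e-12)
        worst = max(worst, rel)
    return worst
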