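"""Jones-Taylor-Thornton (JTT) amino-acid substitution model.

Provides the published JTT exchangeabilities and equilibrium frequencies,
the normalised instantaneous rate matrix Q (scaled to one expected
substitution per site per unit time), and transition probability matrices
P(t) = exp(Qt) computed via the symmetric eigendecomposition trick.

Amino acids are ordered ``ARNDCQEGHILKMFPSTWYV`` throughout, the
conventional order in which the JTT matrix is published.
"""

from __future__ import annotations

import numpy as np

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Published JTT equilibrium amino-acid frequencies (order AA_ORDER).
JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803,
    0.040752, 0.061830, 0.073152, 0.022944, 0.053761,
    0.091904, 0.058676, 0.023826, 0.040126, 0.050901,
    0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()

# Published JTT exchangeabilities: strict lower triangle of the symmetric
# exchangeability matrix in column-major order, i.e. (2,1), (3,1), ...,
# (20,1), (3,2), ..., (20,19), with rows/columns in AA_ORDER.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]


def exchangeability_matrix() -> np.ndarray:
    """Symmetric 20x20 JTT exchangeability matrix (zero diagonal)."""
    s = np.zeros((20, 20))
    # The published list is the lower triangle in column-major order, which
    # by symmetry equals the upper triangle in row-major order.
    s[np.triu_indices(20, k=1)] = _JTT_LOWER
    return s + s.T


def rate_matrix() -> np.ndarray:
    """Normalised JTT rate matrix Q.

    Q[i, j] (i != j) is the instantaneous rate i -> j; rows sum to zero and
    the matrix is scaled so that -sum_i pi_i Q[i, i] == 1, i.e. branch
    lengths are in expected substitutions per site.
    """
    s = exchangeability_matrix()
    q = s * JTT_FREQS[np.newaxis, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(JTT_FREQS * np.diag(q)).sum()
    return q / scale


class _Eigensystem:
    """Cached spectral decomposition of Q for fast exp(Qt)."""

    def __init__(self) -> None:
        q = rate_matrix()
        pi_sqrt = np.sqrt(JTT_FREQS)
        b = (q * pi_sqrt[:, np.newaxis]) / pi_sqrt[np.newaxis, :]
        b = (b + b.T) / 2.0  # symmetric up to round-off
        self.eigvals, v = np.linalg.eigh(b)
        self.left = v / pi_sqrt[:, np.newaxis]      # D^{-1/2} V
        self.right = (v * pi_sqrt[:, np.newaxis]).T  # V^T D^{1/2}


_EIG: _Eigensystem | None = None


def _eig() -> _Eigensystem:
    global _EIG
    if _EIG is None:
        _EIG = _Eigensystem()
    return _EIG


def transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt): P[i, j] is Pr(state j at time t | state i at 0).

    ``t`` is in expected substitutions per site; must be >= 0.
    """
    if t < 0:
        raise ValueError(f"branch length must be non-negative, got {t}")
    e = _eig()
    p = (e.left * np.exp(e.eigvals * t)) @ e.right
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p
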