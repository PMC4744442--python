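"""Independent brute-force implementations used as oracles in tests.

These deliberately avoid the package's own code paths: statistics are
evaluated by explicit elementwise loops, and matrix square roots come from
``scipy.linalg.sqrtm`` (a Schur-based algorithm, independent of the
package's eigendecomposition route).
"""

import numpy as np
import scipy.linalg


def brute_slice_moments(Z, labels, H, ddof=0):
    """Per-slice means/covariances by an explicit python loop."""
    p = Z.shape[1]
    means = np.zeros((H, p))
    covs = np.zeros((H, p, p))
    for s in range(1, H + 1):
        rows = Z[np.asarray(labels) == s]
        ns = len(rows)
        means[s - 1] = sum(rows) / ns
        for i in range(p):
            for j in range(p):
                acc = 0.0
                for r in rows:
                    acc += (r[i] - means[s - 1, i]) * (r[j] - means[s - 1, j])
                covs[s - 1, i, j] = acc / (ns - ddof)
    return means, covs


def brute_T(covs, pooled, props):
    """Elementwise double-loop evaluation of the T-type statistic."""
    H, p, _ = covs.shape
    Ti = np.zeros(p)
    for s in range(H):
        for i in range(p):
            for j in range(p):
                Ti[i] += props[s] * (covs[s, i, j] - pooled[i, j]) ** 2
    return float(Ti.sum()), Ti


def brute_V(covs, means, pooled, props):
    """V-type statistic via scipy's sqrtm and an explicit trace."""
    H = covs.shape[0]
    P_root = np.real(scipy.linalg.sqrtm(pooled))
    total = 0.0
    for s in range(H):
        C = covs[s]
        # PSD repair identical in spirit: clip tiny negative eigenvalues
        w, U = np.linalg.eigh(C)
        C = (U * np.clip(w, 0, None)) @ U.T
        root = np.real(scipy.linalg.sqrtm(C))
        D = root - P_root
        total += props[s] * (np.trace(D @ D) + means[s] @ means[s])
    return float(total)


def brute_V_scalar(variances, means, props):
    """Closed-form V for p=1: sum_s p_s ((sqrt(v_s)-1)^2 + m_s^2)."""
    return float(
        sum(
            w * ((np.sqrt(v) - 1.0) ** 2 + m**2)
            for w, v, m in zip(props, variances, means)
        )
    )
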