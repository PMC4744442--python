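"""Synthetic expression data for the three study designs, plus a size/power harness.

Three scenario families are generated:

* **Binary** — two groups of n/2 samples from p-variate normals N(0, Sigma_1)
  and N(0, Sigma_2).  Group 1 genes are uncorrelated, with unit variances
  (homogeneous) or variances drawn from U(1, 5) (heterogeneous).  Under the
  null Sigma_2 = Sigma_1; under the alternative group 2 redraws its variances
  and the first ``gamma * p`` genes become equi-correlated at rho.

* **Three-class** — three groups of n/3 samples.  Sigma_1 is diagonal with
  U(1, 5) variances; Sigma_2 and Sigma_3 are block-diagonal with four blocks
  of size p/4, U(1, 5) variances, and within each block ``gamma * p / 4``
  equi-correlated genes at rho — the FIRST positions in Sigma_2, the LAST in
  Sigma_3, so the two alternative classes are differentially coexpressed.

* **Continuous** — X ~ MVN(0, Sigma_X) with unit variances, an
  equi-correlated first block of p1 genes, an AR-type block (rho^|i-j|) on
  the next p1, and independence elsewhere.  The phenotype is N(0, 1)
  independent of X (null), or normal with mean x' beta (linear) or
  exp(x' beta) (nonlinear) and unit noise.  beta has ten nonzero entries:
  five random positions in the first block with beta_j ~ N(nu, |nu|) and
  five in the second with beta_j ~ N(-nu, |nu|); nu = 0 gives beta = 0.

Covariances are assembled as D^{1/2} R D^{1/2} (rho acts on correlations) and
checked positive definite at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import InvalidInputError, ScenarioError
from .permutation import PermutationConfig, permutation_test
from .types import ExpressionMatrix, Phenotype


# ---------------------------------------------------------------------------
# scenario definitions


@dataclass
class BinaryScenario:
    n: int = 20
    p: int = 20
    variance_mode: str = "homogeneous"  # or "heterogeneous"
    gamma: float = 0.5
    rho: float = 0.5
    null: bool = False

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ScenarioError(f"n={self.n} must be even (groups of n/2)")
        if self.variance_mode not in ("homogeneous", "heterogeneous"):
            raise ScenarioError(f"unknown variance_mode {self.variance_mode!r}")
        if not (0 <= self.rho < 1):
            raise ScenarioError(f"rho={self.rho} outside [0, 1)")
        if not (0 <= self.gamma <= 1):
            raise ScenarioError(f"gamma={self.gamma} outside [0, 1]")


@dataclass
class ThreeClassScenario:
    n: int = 30
    p: int = 20
    gamma: float = 0.5
    rho: float = 0.5
    null: bool = False

    def __post_init__(self) -> None:
        if self.n % 3:
            raise ScenarioError(f"n={self.n} must be divisible by 3")
        if self.p % 4:
            raise ScenarioError(f"p={self.p} must be divisible by 4 (four blocks)")
        if not (0 <= self.rho < 1):
            raise ScenarioError(f"rho={self.rho} outside [0, 1)")


@dataclass
class ContinuousScenario:
    n: int = 20
    p: int = 20
    p1: int = 5
    rho: float = 0.0
    link: str = "null"  # null | linear | nonlinear
    nu: float = 0.0

    def __post_init__(self) -> None:
        if 2 * self.p1 > self.p:
            raise ScenarioError(f"need 2*p1 <= p, got p1={self.p1}, p={self.p}")
        if self.link not in ("null", "linear", "nonlinear"):
            raise ScenarioError(f"unknown link {self.link!r}")
        if not (0 <= self.rho < 1):
            raise ScenarioError(f"rho={self.rho} outside [0, 1)")
        if self.link != "null" and self.p1 < 5:
            raise ScenarioError("alternative links place 5 signal genes per block; need p1 >= 5")


Scenario = BinaryScenario | ThreeClassScenario | ContinuousScenario


# ---------------------------------------------------------------------------
# covariance construction


def _check_pd(S: np.ndarray, what: str) -> np.ndarray:
    lam_min = float(np.linalg.eigvalsh(S)[0])
    if lam_min <= 0:
        raise ScenarioError(f"{what} is not positive definite (min eig {lam_min:.3e})")
    return S


def _equicorr(p: int, k: int, rho: float, first: bool = True) -> np.ndarray:
    """Correlation matrix with an equi-correlated block of size k at rho."""
    R = np.eye(p)
    idx = np.arange(k) if first else np.arange(p - k, p)
    if k >= 2 and rho != 0:
        R[np.ix_(idx, idx)] = rho
        R[idx, idx] = 1.0
    return R


def _cov_from_corr(R: np.ndarray, variances: np.ndarray) -> np.ndarray:
    d = np.sqrt(variances)
    return d[:, None] * R * d[None, :]


def binary_covariances(
    sc: BinaryScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """(Sigma_1, Sigma_2) for one replicate of the two-group design."""
    p = sc.p
    if sc.variance_mode == "homogeneous":
        v1 = np.ones(p)
    else:
        v1 = rng.uniform(1, 5, p)
    S1 = np.diag(v1)
    if sc.null:
        return S1, S1.copy()
    v2 = rng.uniform(1, 5, p) if sc.variance_mode == "heterogeneous" else np.ones(p)
    k = round(sc.gamma * p)
    R2 = _equicorr(p, k, sc.rho, first=True)
    S2 = _cov_from_corr(R2, v2)
    return _check_pd(S1, "Sigma_1"), _check_pd(S2, "Sigma_2")


def threeclass_covariances(
    sc: ThreeClassScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Sigma_1, Sigma_2, Sigma_3) for one replicate of the three-class design."""
    p, b = sc.p, sc.p // 4
    k = round(sc.gamma * b)
    S1 = np.diag(rng.uniform(1, 5, p))
    mats = [S1]
    for first in (True, False):  # Sigma_2 correlates first k, Sigma_3 last k
        v = rng.uniform(1, 5, p)
        R = np.zeros((p, p))
        rho = 0.0 if sc.null else sc.rho
        for blk in range(4):
            sl = slice(blk * b, (blk + 1) * b)
            R[sl, sl] = _equicorr(b, k, rho, first=first)
        mats.append(_check_pd(_cov_from_corr(R, v), "block covariance"))
    return tuple(mats)


def continuous_covariance(sc: ContinuousScenario) -> np.ndarray:
    """Sigma_X: unit diagonal, equi-correlated block 1..p1, AR block p1+1..2p1."""
    p, p1, rho = sc.p, sc.p1, sc.rho
    S = np.eye(p)
    if p1 >= 2 and rho != 0:
        b1 = slice(0, p1)
        S[b1, b1] = rho
        idx = np.arange(p1, 2 * p1)
        S[np.ix_(idx, idx)] = rho ** np.abs(idx[:, None] - idx[None, :])
        S[np.arange(p), np.arange(p)] = 1.0
    return _check_pd(S, "Sigma_X")


# ---------------------------------------------------------------------------
# dataset generators


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _mvn(rng: np.random.Generator, n: int, S: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(S)
    return rng.standard_normal((n, S.shape[0])) @ L.T


def _wrap(X: np.ndarray) -> ExpressionMatrix:
    n, p = X.shape
    return ExpressionMatrix(
        X, [f"g{j + 1}" for j in range(p)], [f"s{i + 1}" for i in range(n)]
    )


def simulate_binary(sc: BinaryScenario, seed=0) -> tuple[ExpressionMatrix, Phenotype]:
    """One replicate of the two-group design (groups of n/2 samples)."""
    rng = _as_rng(seed)
    S1, S2 = binary_covariances(sc, rng)
    half = sc.n // 2
    X = np.vstack([_mvn(rng, half, S1), _mvn(rng, half, S2)])
    y = np.repeat(["1", "2"], half)
    return _wrap(X), Phenotype(y, "categorical")


def simulate_threeclass(
    sc: ThreeClassScenario, seed=0
) -> tuple[ExpressionMatrix, Phenotype]:
    """One replicate of the three-class design (groups of n/3 samples)."""
    rng = _as_rng(seed)
    S1, S2, S3 = threeclass_covariances(sc, rng)
    third = sc.n // 3
    X = np.vstack([_mvn(rng, third, S) for S in (S1, S2, S3)])
    y = np.repeat(["1", "2", "3"], third)
    return _wrap(X), Phenotype(y, "categorical")


def draw_beta(sc: ContinuousScenario, rng: np.random.Generator) -> np.ndarray:
    """Sparse regression coefficients: 5 signal genes per correlated block."""
    beta = np.zeros(sc.p)
    if sc.nu == 0:
        return beta
    sd = np.sqrt(abs(sc.nu))
    pos1 = rng.choice(sc.p1, size=5, replace=False)
    pos2 = sc.p1 + rng.choice(sc.p1, size=5, replace=False)
    beta[pos1] = rng.normal(sc.nu, sd, 5)
    beta[pos2] = rng.normal(-sc.nu, sd, 5)
    return beta


def simulate_continuous(
    sc: ContinuousScenario, seed=0
) -> tuple[ExpressionMatrix, Phenotype]:
    """One replicate of the continuous-phenotype design."""
    rng = _as_rng(seed)
    X = _mvn(rng, sc.n, continuous_covariance(sc))
    if sc.link == "null" or sc.nu == 0:
        y = rng.normal(0.0, 1.0, sc.n)
    else:
        eta = X @ draw_beta(sc, rng)
        mean = eta if sc.link == "linear" else np.exp(eta)
        y = mean + rng.normal(0.0, 1.0, sc.n)
    return _wrap(X), Phenotype(y, "continuous")


def simulate(sc: Scenario, seed=0) -> tuple[ExpressionMatrix, Phenotype]:
    """Dispatch on scenario type."""
    if isinstance(sc, BinaryScenario):
        return simulate_binary(sc, seed)
    if isinstance(sc, ThreeClassScenario):
        return simulate_threeclass(sc, seed)
    if isinstance(sc, ContinuousScenario):
        return simulate_continuous(sc, seed)
    raise InvalidInputError(f"unknown scenario type {type(sc).__name__}")


# ---------------------------------------------------------------------------
# size / power evaluation


@dataclass
class SizePowerResult:
    """Empirical rejection rate of one test under one scenario."""

    rejection_rate: float
    standard_error: float
    n_datasets: int
    alpha: float
    statistic_name: str
    p_values: np.ndarray = field(repr=False)


def estimate_size_power(
    sc: Scenario,
    statistic_name: str = "T",
    n_datasets: int = 1000,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    slices: int | str | None = None,
    standardize: str = "auto",
    progress: Callable[[int], None] | None = None,
) -> SizePowerResult:
    """Monte-Carlo rejection rate of a permutation test under a scenario.

    Each dataset gets an independent generator stream spawned from ``seed``,
    so the result is deterministic in ``seed`` and independent of evaluation
    order.  The binomial standard error sqrt(r (1 - r) / n_datasets) is
    attached.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_datasets)
    pvals = np.empty(n_datasets)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        X, y = simulate(sc, rng)
        perm_seed = int(rng.integers(2**31))
        cfg = PermutationConfig(
            n_permutations=n_permutations,
            seed=perm_seed,
            statistic_name=statistic_name,
            standardize=standardize,
        )
        pvals[i] = permutation_test(X, y, cfg, slices=slices).p_value
        if progress is not None:
            progress(i + 1)
    rate = float(np.mean(pvals <= alpha))
    se = float(np.sqrt(rate * (1 - rate) / n_datasets))
    return SizePowerResult(rate, se, n_datasets, alpha, statistic_name, pvals)


def calibration_limits(
    truth: float, n_replicates: int = 1000, confidence: float = 0.975
) -> tuple[float, float]:
    """Binomial SE of an empirical rate and its upper normal quantile limit.

    For a true rate ``truth`` estimated from ``n_replicates`` Monte-Carlo
    datasets, returns (SE, truth + z * SE) with z the ``confidence`` standard
    normal quantile — the bound an empirical type-I-error rate should stay
    under if the test holds its level.
    """
    from scipy.stats import norm

    se = float(np.sqrt(truth * (1 - truth) / n_replicates))
    return se, truth + float(norm.ppf(confidence)) * se
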