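"""No-replicate differential expression by simulated technical replicates.

With one library per condition there is no empirical dispersion to
estimate. Instead, technical replicates are simulated from each observed
library: replicate ``r`` is a multinomial draw over the library's count
proportions at a reduced depth (a fraction ``pnr`` of the library's
counts, jittered by ``v``). Every within-condition pair of simulated
replicates then yields, per miRNA, a noise point (|M|, D) — how large a
log-ratio and absolute difference pure resampling noise produces. The
observed between-library signal (M, D) of each miRNA is ranked against the
pooled noise cloud:

    P(DE) = fraction of noise points (m, d) with m < |M| and d < D

(strict on both coordinates, so ties favour "not DE"). miRNAs with
P > 0.8 are called differentially expressed, the sign of M giving the
direction. P is an empirical exceedance probability, not a p-value, and
no multiple-testing correction applies.

Simulated counts are put on the observed RPKM scale with each miRNA's
observed RPKM/count ratio (depth-corrected), so noise and signal are
directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .quantification import PairwiseContrast

DEFAULT_NSS = 5       # simulated replicates per condition
DEFAULT_PNR = 0.2     # simulated depth as a fraction of library counts
DEFAULT_V = 0.02      # uniform jitter on the simulated depth
DEFAULT_THRESHOLD = 0.8
DEFAULT_PSEUDO_COUNTS = 0.5

Direction = Literal["up_in_1", "up_in_2", "not_DE"]


@dataclass(frozen=True)
class SimParams:
    """Replicate-simulation constants.

    nss : simulated replicates per condition (>= 2)
    pnr : simulated depth as a fraction of the library's summed counts
    v   : half-width of the uniform jitter on that fraction
    seed: RNG seed for reproducibility
    """

    nss: int = DEFAULT_NSS
    pnr: float = DEFAULT_PNR
    v: float = DEFAULT_V
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nss < 2:
            raise ValueError(f"nss must be >= 2, got {self.nss}")
        if not 0 < self.pnr <= 1:
            raise ValueError(f"pnr must be in (0, 1], got {self.pnr}")
        if not 0 <= self.v < self.pnr:
            raise ValueError(f"v must satisfy 0 <= v < pnr, got {self.v}")


@dataclass(frozen=True)
class NoiseCloud:
    """Pooled (|M|, D) pairs from within-condition replicate contrasts."""

    pairs: np.ndarray  # shape (n_pairs, 2): columns |M|, D

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("pairs must be an (n, 2) array")
        if not np.all(np.isfinite(pairs)) or np.any(pairs < 0):
            raise ValueError("noise pairs must be finite and non-negative")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class DECall:
    """Per-miRNA differential-expression call."""

    name: str
    M: float
    D: float
    probability: float
    direction: Direction


def simulate_replicates(counts: Sequence[int], library_total: int,
                        params: SimParams,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw simulated technical replicates from one library's counts.

    Each replicate is multinomial over ``counts / sum(counts)`` with size
    ``round(depth_r * sum(counts))``, depth_r uniform in
    [pnr - v, pnr + v]. Returns an integer matrix (features x nss).
    ``library_total`` is carried for normalization and does not enter the
    draw.
    """
    counts = np.asarray(counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total_counts = int(counts.sum())
    if total_counts == 0:
        raise ValueError("all counts are zero; nothing to simulate")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    probs = counts / total_counts
    depths = rng.uniform(params.pnr - params.v, params.pnr + params.v,
                         size=params.nss)
    sizes = np.rint(depths * total_counts).astype(np.int64)
    sim = np.empty((len(counts), params.nss), dtype=np.int64)
    for r in range(params.nss):
        sim[:, r] = rng.multinomial(sizes[r], probs)
    return sim


def observed_scale_normalizer(observed_rpkm: Sequence[float],
                              observed_counts: Sequence[int],
                              ) -> Callable[[np.ndarray], np.ndarray]:
    """Build a counts->RPKM map anchored on observed RPKM/count ratios.

    For miRNA i with observed count c_i and RPKM x_i, a simulated count k
    at replicate depth S maps to ``k * (x_i / c_i) * (sum(c) / S)`` so its
    expectation reproduces x_i. Features observed at zero fall back to the
    median per-count factor.
    """
    x = np.asarray(observed_rpkm, dtype=float)
    c = np.asarray(observed_counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(c > 0, x / np.maximum(c, 1e-300), np.nan)
    if np.all(np.isnan(factor)):
        raise ValueError("no feature with a positive observed count")
    factor = np.where(np.isnan(factor), np.nanmedian(factor), factor)
    total_counts = float(c.sum())

    def normalize(column: np.ndarray) -> np.ndarray:
        column = np.asarray(column, dtype=float)
        size = column.sum()
        if size <= 0:
            raise ValueError("simulated replicate has zero depth")
        return column * factor * (total_counts / size)

    normalize.per_count_factor = factor  # type: ignore[attr-defined]
    normalize.total_counts = total_counts  # type: ignore[attr-defined]
    return normalize


def _pairwise_noise(sim: np.ndarray, normalize, pseudo) -> list[np.ndarray]:
    nss = sim.shape[1]
    rpkm_cols = [normalize(sim[:, r]) for r in range(nss)]
    pseudo_arr = np.broadcast_to(np.asarray(pseudo, dtype=float),
                                 (sim.shape[0],))
    chunks = []
    for a, b in combinations(range(nss), 2):
        xa, xb = rpkm_cols[a], rpkm_cols[b]
        xa_p = np.where(xa > 0, xa, pseudo_arr)
        xb_p = np.where(xb > 0, xb, pseudo_arr)
        m = np.abs(np.log2(xa_p / xb_p))
        d = np.abs(xa - xb)
        chunks.append(np.column_stack([m, d]))
    return chunks


def build_noise(sim1: np.ndarray, sim2: np.ndarray,
                normalizer_1, normalizer_2=None,
                pseudo: float | np.ndarray = 1e-6) -> NoiseCloud:
    """Pool within-condition (|M|, D) pairs from both conditions' replicates.

    ``normalizer_1``/``normalizer_2`` map a simulated count column to RPKM
    (one per condition; the first is reused if the second is omitted).
    ``pseudo`` (scalar or per-feature) replaces zero RPKMs inside the
    log-ratio only. Cloud size = n_features x 2 x C(nss, 2).
    """
    if sim1.shape[0] != sim2.shape[0]:
        raise ValueError("conditions must share the feature set")
    if sim1.shape[1] < 2 or sim2.shape[1] < 2:
        raise ValueError("need at least two simulated replicates per condition")
    if normalizer_2 is None:
        normalizer_2 = normalizer_1
    chunks = _pairwise_noise(sim1, normalizer_1, pseudo)
    chunks += _pairwise_noise(sim2, normalizer_2, pseudo)
    return NoiseCloud(np.concatenate(chunks, axis=0))


def de_probability(signal: tuple[float, float], cloud: NoiseCloud) -> float:
    """Fraction of noise pairs strictly dominated by the signal (M, D)."""
    if len(cloud) == 0:
        raise ValueError("empty noise cloud")
    m_sig, d_sig = abs(signal[0]), signal[1]
    pairs = cloud.pairs
    return float(np.mean((pairs[:, 0] < m_sig) & (pairs[:, 1] < d_sig)))


def _de_probabilities(m: np.ndarray, d: np.ndarray, cloud: NoiseCloud) -> np.ndarray:
    pairs = cloud.pairs
    dominated = (pairs[None, :, 0] < np.abs(m)[:, None]) & \
                (pairs[None, :, 1] < d[:, None])
    return dominated.mean(axis=1)


def call_de(contrasts: Sequence[PairwiseContrast],
            probabilities: Sequence[float],
            threshold: float = DEFAULT_THRESHOLD) -> list[DECall]:
    """Threshold probabilities into direction calls.

    P > threshold with M > 0 is up in library 1, with M < 0 up in
    library 2; anything else is not DE. Output is ordered up_in_1,
    up_in_2, not_DE, each block by descending |M| (the published table
    ordering).
    """
    if len(contrasts) != len(probabilities):
        raise ValueError("contrasts and probabilities differ in length")
    calls = []
    for ct, p in zip(contrasts, probabilities):
        if not 0 <= p <= 1:
            raise ValueError(f"probability {p} outside [0, 1]")
        if p > threshold:
            direction: Direction = "up_in_1" if ct.M > 0 else "up_in_2"
        else:
            direction = "not_DE"
        calls.append(DECall(ct.name, ct.M, ct.D, float(p), direction))
    order = {"up_in_1": 0, "up_in_2": 1, "not_DE": 2}
    calls.sort(key=lambda c: (order[c.direction], -abs(c.M), c.name))
    return calls


class NoiseSimDE(BaseEstimator):
    """No-replicate differential expression between two libraries.

    ``fit`` takes an expression table (index = miRNA, columns
    ``counts_<lib>`` and ``rpkm_<lib>`` for the two libraries), simulates
    technical replicates from each library's counts, builds the pooled
    noise cloud and ranks each miRNA's observed (M, D) signal against it.

    Parameters
    ----------
    nss, pnr, v : simulation constants, see :class:`SimParams`.
    threshold : float
        DE calls require probability > threshold.
    pseudo_counts : float
        Zero RPKMs are replaced by this many counts (converted to RPKM
        with the miRNA's own scale factor) inside log-ratios.
    random_state : int or numpy Generator, optional

    Attributes
    ----------
    results_ : DataFrame with columns P, M, D, direction (per miRNA).
    noise_cloud_ : NoiseCloud used for the ranking.
    calls_ : list of DECall in published-table order.
    n_up_1_, n_up_2_ : number of calls in each direction.
    """

    def __init__(self, nss: int = DEFAULT_NSS, pnr: float = DEFAULT_PNR,
                 v: float = DEFAULT_V, threshold: float = DEFAULT_THRESHOLD,
                 pseudo_counts: float = DEFAULT_PSEUDO_COUNTS,
                 random_state=None):
        self.nss = nss
        self.pnr = pnr
        self.v = v
        self.threshold = threshold
        self.pseudo_counts = pseudo_counts
        self.random_state = random_state

    def _libraries(self, expr: pd.DataFrame) -> tuple[str, str]:
        libs = []
        for col in expr.columns:
            if col.startswith("counts_"):
                lib = col[len("counts_"):]
                if f"rpkm_{lib}" in expr.columns:
                    libs.append(lib)
        if len(libs) != 2:
            raise ValueError(
                "expression table must carry counts_/rpkm_ columns for "
                f"exactly two libraries, found {libs}")
        return libs[0], libs[1]

    def fit(self, X: pd.DataFrame, y=None) -> "NoiseSimDE":
        expr = X
        lib1, lib2 = self._libraries(expr)
        rng = (self.random_state if isinstance(self.random_state, np.random.Generator)
               else np.random.default_rng(self.random_state))
        params = SimParams(nss=self.nss, pnr=self.pnr, v=self.v)

        c1 = expr[f"counts_{lib1}"].to_numpy(dtype=np.int64)
        c2 = expr[f"counts_{lib2}"].to_numpy(dtype=np.int64)
        x1 = expr[f"rpkm_{lib1}"].to_numpy(dtype=float)
        x2 = expr[f"rpkm_{lib2}"].to_numpy(dtype=float)

        norm1 = observed_scale_normalizer(x1, c1)
        norm2 = observed_scale_normalizer(x2, c2)
        pseudo1 = self.pseudo_counts * norm1.per_count_factor
        pseudo2 = self.pseudo_counts * norm2.per_count_factor

        sim1 = simulate_replicates(c1, int(c1.sum()), params, rng=rng)
        sim2 = simulate_replicates(c2, int(c2.sum()), params, rng=rng)
        # zero substitution inside the cloud uses each condition's own scale
        cloud1 = NoiseCloud(np.concatenate(
            _pairwise_noise(sim1, norm1, pseudo1), axis=0))
        cloud2 = NoiseCloud(np.concatenate(
            _pairwise_noise(sim2, norm2, pseudo2), axis=0))
        self.noise_cloud_ = NoiseCloud(
            np.concatenate([cloud1.pairs, cloud2.pairs], axis=0))

        # observed signal; zero RPKM -> pseudo of the zero side's library
        contrasts = []
        for i, name in enumerate(expr.index):
            x1p = x1[i] if x1[i] > 0 else pseudo1[i]
            x2p = x2[i] if x2[i] > 0 else pseudo2[i]
            contrasts.append(PairwiseContrast(
                name=name, x1=x1[i], x2=x2[i],
                M=float(np.log2(x1p / x2p)), D=float(abs(x1[i] - x2[i]))))
        m = np.array([ct.M for ct in contrasts])
        d = np.array([ct.D for ct in contrasts])
        probs = _de_probabilities(m, d, self.noise_cloud_)

        self.library_1_, self.library_2_ = lib1, lib2
        self.contrasts_ = contrasts
        self.probabilities_ = probs
        self.calls_ = call_de(contrasts, probs, self.threshold)
        self.results_ = pd.DataFrame(
            {
                "P": [c.probability for c in self.calls_],
                "M": [c.M for c in self.calls_],
                "D": [c.D for c in self.calls_],
                "direction": [c.direction for c in self.calls_],
            },
            index=pd.Index([c.name for c in self.calls_], name="mirna"),
        )
        self.n_up_1_ = sum(c.direction == "up_in_1" for c in self.calls_)
        self.n_up_2_ = sum(c.direction == "up_in_2" for c in self.calls_)
        return self

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        """Direction labels in the row order of ``results_``."""
        if not hasattr(self, "results_"):
            raise ValueError("fit the estimator first")
        return self.results_["direction"].to_numpy()


def run_noiseq_sim(expr: pd.DataFrame, seed: int | None = None,
                   **params) -> NoiseSimDE:
    """One-call wrapper: fit :class:`NoiseSimDE` on an expression table."""
    est = NoiseSimDE(random_state=seed, **params)
    return est.fit(expr)
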