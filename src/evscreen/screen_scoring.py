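"""Gene-level scoring of EV-release screens.

The statistic follows the casTLE family of maximum-likelihood screen
scores. Per element, enrichment is the median-centred log2 ratio of
treated over reference counts (EV phenotype: Cas9-EV vs WT-EV; growth
phenotype: cells at 48 h vs 0 h). Control elements (non-targeting and
safe-targeting) define a null density f0 of enrichments, estimated by a
Gaussian kernel. A gene's elements are modelled as each expressing an
unknown fraction t in [0, 1] of the gene's maximal effect e, so the
per-element likelihood marginalises t over a uniform grid:

    L_i(e) = (1/m) * sum_t f0(rho_i - t * e)

The gene effect is the grid argmax of the summed log-likelihood, i.e. the
largest phenotype such that the elements most plausibly lie between it and
zero; the confidence score is the log-likelihood ratio 2*(l(e_hat) - l(0)),
floored at zero. Significance comes from permutations: random same-size
element sets drawn from all targeting elements, scored identically.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deconvolution import CountMatrix
from .errors import EvscreenError
from .library_model import Library


def _default_effect_grid() -> np.ndarray:
    return np.round(np.arange(-8.0, 8.0 + 1e-9, 0.05), 10)


@dataclass
class ScoringConfig:
    """Knobs of the scoring pipeline (defaults are the screen's)."""

    pseudocount: float = 0.5
    low_count_min: int = 10
    effect_grid: np.ndarray = field(default_factory=_default_effect_grid)
    efficacy_grid_size: int = 21
    n_permutations: int = 10_000
    effect_cutoff: float = 2.0
    #: 1.5 for a focused sublibrary-style analysis; 2.5 genome-wide.
    logp_cutoff: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.effect_grid = np.asarray(self.effect_grid, dtype=float)
        if self.effect_grid.size == 0 or self.efficacy_grid_size < 1:
            raise EvscreenError("grids must be non-empty")
        if not np.any(self.effect_grid == 0.0):
            raise EvscreenError("effect_grid must contain 0")
        if self.n_permutations < 0:
            raise EvscreenError("n_permutations must be >= 0")


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentTable:
    """Per-element enrichment rho with library annotation.

    ``data`` is indexed by element_id with columns gene, category, rho.
    Elements filtered for low reference counts are absent from ``data`` and
    tallied in ``n_filtered``.
    """

    data: pd.DataFrame
    treated: str
    reference: str
    n_filtered: int

    @property
    def rho(self) -> pd.Series:
        return self.data["rho"]

    def control_rho(self) -> np.ndarray:
        mask = self.data["category"].isin(["nontargeting", "safe_targeting"])
        return self.data.loc[mask, "rho"].to_numpy()

    def targeting_rho(self) -> pd.Series:
        return self.data.loc[self.data["category"] == "targeting", "rho"]


def compute_enrichment(counts: CountMatrix, treated: str, reference: str,
                       lib: Library, cfg: ScoringConfig | None = None) -> EnrichmentTable:
    """Median-centred log2 count ratios, filtering low reference counts.

    Elements with reference count < ``low_count_min`` are excluded before
    the ratio and before the median used for centring.
    """
    cfg = cfg or ScoringConfig()
    for s in (treated, reference):
        if s not in counts.counts.columns:
            raise EvscreenError(f"sample {s!r} not in count matrix")
    lib_df = lib.to_frame().set_index("element_id")
    shared = counts.counts.index.intersection(lib_df.index)
    t = counts.counts.loc[shared, treated].astype(float)
    r = counts.counts.loc[shared, reference].astype(float)
    keep = r >= cfg.low_count_min
    n_filtered = int((~keep).sum()) + (len(lib_df) - len(shared))
    t, r = t[keep], r[keep]
    if t.empty:
        raise EvscreenError("no elements pass the low-count filter")
    rho = np.log2((t + cfg.pseudocount) / (r + cfg.pseudocount))
    rho = rho - np.median(rho)
    data = pd.DataFrame({
        "gene": lib_df.loc[rho.index, "gene"],
        "category": lib_df.loc[rho.index, "category"],
        "rho": rho,
    })
    return EnrichmentTable(data=data, treated=treated, reference=reference,
                           n_filtered=n_filtered)


# ---------------------------------------------------------------------------
# Null model
# ---------------------------------------------------------------------------

DENSITY_FLOOR = 1e-12


@dataclass
class NullModel:
    """Control-element enrichment density on a fixed grid (linear interp)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_controls: int

    def pdf(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self.density,
                         left=DENSITY_FLOOR, right=DENSITY_FLOOR)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        return np.log(self.pdf(x))


def fit_null(enr: EnrichmentTable | np.ndarray, min_controls: int = 50,
             grid_step: float = 0.01, grid_pad: float = 9.0,
             bandwidth_floor: float = 1e-3) -> NullModel:
    """Gaussian-KDE null over control enrichments (Scott's-rule bandwidth).

    The density is evaluated on a uniform grid padded well beyond the
    control range (so that shifted arguments rho - t*e stay on-grid),
    floored at 1e-12 and renormalised to integrate to one.
    """
    ctrl = enr.control_rho() if isinstance(enr, EnrichmentTable) else np.asarray(enr, float)
    if ctrl.size < min_controls:
        raise EvscreenError(
            f"only {ctrl.size} control elements post-filter (< {min_controls}); "
            "simulate or include more controls")
    spread = float(np.std(ctrl))
    grid = np.arange(ctrl.min() - grid_pad, ctrl.max() + grid_pad + grid_step, grid_step)
    if spread == 0.0:
        warnings.warn("degenerate control distribution; applying bandwidth floor",
                      RuntimeWarning, stacklevel=2)
        bw = bandwidth_floor
        density = stats.norm.pdf(grid, loc=float(ctrl[0]), scale=bw)
    else:
        kde = stats.gaussian_kde(ctrl, bw_method="scott")
        bw = max(float(kde.factor * spread), bandwidth_floor)
        if bw > float(kde.factor * spread):
            kde.set_bandwidth(bw / spread)
        density = kde(grid)
    density = np.maximum(density, DENSITY_FLOOR)
    density /= np.trapezoid(density, grid)
    return NullModel(grid=grid, density=density, bandwidth=bw, n_controls=int(ctrl.size))


# ---------------------------------------------------------------------------
# Gene effect likelihood
# ---------------------------------------------------------------------------

def element_curves(rho: np.ndarray, null: NullModel, cfg: ScoringConfig,
                   chunk: int = 1024) -> np.ndarray:
    """Per-element log-likelihood curves over the effect grid, shape (k, E).

    curve[i, j] = log( mean over efficacy t of f0(rho_i - t * e_j) ).
    Gene-level curves are sums of rows, which makes permutation scoring a
    cheap fancy-indexed sum.
    """
    rho = np.asarray(rho, dtype=float)
    E = cfg.effect_grid
    T = np.linspace(0.0, 1.0, cfg.efficacy_grid_size)
    te = T[:, None] * E[None, :]  # (m, E)
    out = np.empty((rho.size, E.size))
    for s in range(0, rho.size, chunk):
        block = rho[s:s + chunk]
        args = block[:, None, None] - te[None, :, :]
        out[s:s + chunk] = np.log(null.pdf(args).mean(axis=1))
    return out


def _argmax_effect(ll: np.ndarray, grid: np.ndarray) -> int:
    """Grid argmax with ties broken towards smaller |e|, then negative e."""
    best = ll.max()
    tied = np.flatnonzero(ll == best)
    order = np.lexsort((grid[tied], np.abs(grid[tied])))
    return int(tied[order[0]])


def gene_effect_from_curve(ll: np.ndarray, cfg: ScoringConfig) -> tuple[float, float]:
    """(effect, score) from a gene's summed log-likelihood curve."""
    grid = cfg.effect_grid
    i0 = int(np.flatnonzero(grid == 0.0)[0])
    ih = _argmax_effect(ll, grid)
    score = max(0.0, 2.0 * (ll[ih] - ll[i0]))
    return float(grid[ih]), float(score)


def gene_effect(gene_enrichments: Sequence[float], null: NullModel,
                cfg: ScoringConfig | None = None) -> tuple[float, float]:
    """Maximum-likelihood effect and log-likelihood-ratio score for one gene."""
    cfg = cfg or ScoringConfig()
    rho = np.asarray(list(gene_enrichments), dtype=float)
    if rho.size == 0:
        raise EvscreenError("gene has no elements")
    ll = element_curves(rho, null, cfg).sum(axis=0)
    return gene_effect_from_curve(ll, cfg)


def _perm_scores(curves: np.ndarray, k: int, n_perm: int, cfg: ScoringConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Null score distribution for gene size k: random k-sets from the
    targeting pool (sampled with replacement across the pool), scored the
    same way as observed genes."""
    grid = cfg.effect_grid
    i0 = int(np.flatnonzero(grid == 0.0)[0])
    N = curves.shape[0]
    out = np.empty(n_perm)
    chunk = max(1, 25_000_000 // (k * grid.size))
    for s in range(0, n_perm, chunk):
        b = min(chunk, n_perm - s)
        idx = rng.integers(0, N, size=(b, k))
        ll = curves[idx].sum(axis=1)  # (b, E)
        out[s:s + b] = np.maximum(0.0, 2.0 * (ll.max(axis=1) - ll[:, i0]))
    return out


def permutation_pvalues(observed: Mapping[str, tuple[float, int]],
                        targeting_curves: np.ndarray,
                        cfg: ScoringConfig | None = None) -> pd.Series:
    """Permutation p-values per gene.

    ``observed`` maps gene -> (score, n_elements). For each distinct gene
    size k the null score distribution is simulated once (seeded, cached)
    and p = (1 + #{perm >= observed}) / (n_permutations + 1).
    """
    cfg = cfg or ScoringConfig()
    if cfg.n_permutations < 1:
        raise EvscreenError("n_permutations must be >= 1 for p-values")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.rng_seed, 0x7065726d]))
    cache: dict[int, np.ndarray] = {}
    p = {}
    for gene, (score, k) in observed.items():
        if k not in cache:
            cache[k] = np.sort(_perm_scores(targeting_curves, k, cfg.n_permutations,
                                            cfg, rng))
        null_scores = cache[k]
        n_ge = null_scores.size - np.searchsorted(null_scores, score, side="left")
        p[gene] = (1.0 + n_ge) / (cfg.n_permutations + 1.0)
    return pd.Series(p, name="p")


def combine_ll_curves(curves: Sequence[np.ndarray]) -> np.ndarray:
    """Sum per-replicate log-likelihood curves (grids must match in length)."""
    first = np.asarray(curves[0], dtype=float)
    for c in curves[1:]:
        c = np.asarray(c, dtype=float)
        if c.shape != first.shape:
            raise EvscreenError("effect grids differ between replicates")
        first = first + c
    return first


def combine_replicates(curves: Sequence[np.ndarray],
                       cfg: ScoringConfig | None = None) -> tuple[float, float, np.ndarray]:
    """Single effect consistent with all replicates.

    Sums the replicates' log-likelihood curves and re-derives (effect,
    score); returns the combined curve too so p-values can be recomputed
    against a combined permutation pool.
    """
    cfg = cfg or ScoringConfig()
    ll = combine_ll_curves(curves)
    e, score = gene_effect_from_curve(ll, cfg)
    return e, score, ll


# ---------------------------------------------------------------------------
# Full screen scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneResult:
    gene: str
    effect: float
    score: float
    p: float
    neg_log_p: float
    n_elements: int
    hit: bool
    direction: str  # "activator", "suppressor" or "none"


def call_hits(results: pd.DataFrame, cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Flag hits: |effect| >= cutoff (inclusive) and -log10 p > threshold.

    Negative effects mark activators of EV release (knockout decreases
    barcode output); positive effects mark suppressors.
    """
    cfg = cfg or ScoringConfig()
    out = results.copy()
    big = (out["effect"] <= -cfg.effect_cutoff) | (out["effect"] >= cfg.effect_cutoff)
    out["hit"] = big & (out["neg_log_p"] > cfg.logp_cutoff)
    out["direction"] = np.where(out["effect"] < 0, "activator",
                                np.where(out["effect"] > 0, "suppressor", "none"))
    return out


def score_screen(counts: CountMatrix, lib: Library,
                 comparisons: Sequence[tuple[str, str]],
                 cfg: ScoringConfig | None = None) -> pd.DataFrame:
    """Score a screen from counts: enrichment, null fit, per-gene effects,
    permutation p-values and hit calls, combining replicates by summing
    their log-likelihood curves.

    ``comparisons`` lists (treated, reference) sample pairs, one per
    replicate. Returns a gene-indexed DataFrame with columns effect, score,
    p, neg_log_p, n_elements, hit, direction.
    """
    cfg = cfg or ScoringConfig()
    if not comparisons:
        raise EvscreenError("need at least one (treated, reference) pair")

    rep_curves: list[pd.DataFrame] = []
    for treated, reference in comparisons:
        enr = compute_enrichment(counts, treated, reference, lib, cfg)
        null = fit_null(enr)
        curves = element_curves(enr.rho.to_numpy(), null, cfg)
        rep_curves.append(pd.DataFrame(curves, index=enr.data.index))
        last_enr = enr

    shared = rep_curves[0].index
    for rc in rep_curves[1:]:
        shared = shared.intersection(rc.index)
    if shared.empty:
        raise EvscreenError("no elements shared across replicates post-filter")
    combined = sum(rc.loc[shared].to_numpy() for rc in rep_curves)
    ann = last_enr.data.loc[shared]

    is_targeting = (ann["category"] == "targeting").to_numpy()
    targeting_curves = combined[is_targeting]
    genes = ann.loc[is_targeting, "gene"]

    records = []
    observed: dict[str, tuple[float, int]] = {}
    gene_rows: dict[str, np.ndarray] = {}
    for gene, rows in genes.groupby(genes).groups.items():
        pos = ann.index.get_indexer(rows)
        ll = combined[pos].sum(axis=0)
        e, score = gene_effect_from_curve(ll, cfg)
        observed[gene] = (score, len(pos))
        records.append({"gene": gene, "effect": e, "score": score,
                        "n_elements": len(pos)})
    results = pd.DataFrame(records).set_index("gene")

    if cfg.n_permutations >= 1:
        p = permutation_pvalues(observed, targeting_curves, cfg)
        results["p"] = p
    else:
        results["p"] = np.nan
    results["neg_log_p"] = -np.log10(results["p"])
    results = call_hits(results, cfg)
    return results[["effect", "score", "p", "neg_log_p", "n_elements", "hit", "direction"]]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def qc_concordance(counts: CountMatrix, sample_a: str, sample_b: str,
                   pseudocount: float = 0.5) -> float:
    """R-squared of log2(count + pseudocount) between two samples."""
    a = counts.counts[sample_a].astype(float)
    b = counts.counts[sample_b].astype(float)
    if len(a) < 2:
        raise EvscreenError("need >= 2 shared elements")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    r = np.corrcoef(la, lb)[0, 1]
    return float(r ** 2)


def qc_growth_vs_ev(results_growth: pd.DataFrame, results_ev: pd.DataFrame) -> pd.DataFrame:
    """Pair growth and EV effect estimates per gene for correlation/plotting."""
    merged = pd.DataFrame({
        "effect_growth": results_growth["effect"],
        "effect_ev": results_ev["effect"],
        "score_growth": results_growth["score"],
        "score_ev": results_ev["score"],
    }).dropna()
    if len(merged) < 2:
        raise EvscreenError("need >= 2 shared genes")
    merged.attrs["pearson_r"] = float(
        np.corrcoef(merged["effect_growth"], merged["effect_ev"])[0, 1])
    return merged
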