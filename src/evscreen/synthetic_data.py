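"""Synthetic screens with ground truth.

The generator reproduces the statistical structure the screen design
assumes, so that every downstream stage can be tested against known truth:

* per-element cellular abundance, log-normal (``sigma_cell``, natural-log
  scale), modelling expression/fitness heterogeneity of the infected pool;
* per-barcode EV packaging bias, log-normal (``sigma_pack``), modelling
  sequence-intrinsic differences in exosomal sorting — this is what makes
  cellular and EV abundances nearly uncorrelated, and it cancels exactly
  in the Cas9-vs-WT EV comparison because both genotypes share barcodes;
* per-gene EV effects (log2 units) realised per element through a guide
  efficacy t ~ Uniform[0.5, 1], so knockout of a gene with effect e
  multiplies its elements' EV output by 2**(t*e) in Cas9 cells only;
* independent per-gene growth effects acting on cellular abundance
  between the 0 h and 48 h cellular samples (Cas9 only);
* multinomial sequencing noise at a configured depth.

Reads can be emitted as FASTQ (mature bEXOmiR reads for EV/RNA samples,
anchored protospacer reads for DNA samples) with per-base substitution
errors, together with a truth table of read origins.
"""

from __future__ import annotations

import gzip
import zlib
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._encoding import BASES
from .deconvolution import DEFAULT_SGRNA_ANCHOR, CountMatrix
from .errors import EvscreenError, FeasibilityError
from .library_model import Library
from .screen_scoring import qc_concordance
from .sequence_design import EXO_MOTIF

#: 3' adapter ligated to small RNAs during library prep (TruSeq small RNA).
DEFAULT_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _parse_sample(name: str) -> tuple[str, str, int | None]:
    """Split a sample name like ``Cas9_EV_rep1`` or ``Cas9_cells_t48_rep2``
    into (genotype, compartment, timepoint)."""
    parts = name.split("_")
    genotype = parts[0]
    compartment = parts[1]
    if genotype not in ("WT", "Cas9") or compartment not in ("EV", "cells"):
        raise EvscreenError(f"cannot parse sample name {name!r}")
    timepoint = None
    for p in parts[2:]:
        if p.startswith("t") and p[1:].isdigit():
            timepoint = int(p[1:])
    return genotype, compartment, timepoint


@dataclass
class ScreenSimulation:
    """Generative model of one pooled screen (see module docstring)."""

    library: Library
    cellular_abundance: np.ndarray
    packaging_bias: np.ndarray
    guide_efficacy: np.ndarray
    gene_effects: dict[str, float]
    growth_effects: dict[str, float]
    depth: int
    error_rate: float
    rng_seed: int
    sigma_cell: float
    sigma_pack: float

    @classmethod
    def create(cls, library: Library, gene_effects: Mapping[str, float] | None = None,
               growth_effects: Mapping[str, float] | None = None,
               sigma_cell: float = 1.0, sigma_pack: float = 2.4,
               efficacy_range: tuple[float, float] = (0.5, 1.0),
               depth: int | None = None, error_rate: float = 0.001,
               seed: int = 0) -> "ScreenSimulation":
        """Draw abundances, biases and efficacies for a library.

        ``depth`` defaults to 500 reads per element per sample. The default
        ``sigma_pack`` = 2.4 puts the cell-vs-EV log-abundance R^2 near
        sigma_cell^2 / (sigma_cell^2 + sigma_pack^2) ~= 0.15, the weak
        correlation regime the screen operates in; :func:`tune_bias`
        calibrates it against a measured band.
        """
        n = len(library)
        if n == 0:
            raise EvscreenError("library is empty")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0x73696d]))
        abundance = np.exp(rng.normal(0.0, sigma_cell, size=n))
        bias = np.exp(rng.normal(0.0, sigma_pack, size=n)) if sigma_pack > 0 \
            else np.ones(n)
        lo, hi = efficacy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise EvscreenError("efficacy_range must lie within [0, 1]")
        efficacy = rng.uniform(lo, hi, size=n)
        return cls(
            library=library,
            cellular_abundance=abundance,
            packaging_bias=bias,
            guide_efficacy=efficacy,
            gene_effects=dict(gene_effects or {}),
            growth_effects=dict(growth_effects or {}),
            depth=depth if depth is not None else 500 * n,
            error_rate=error_rate,
            rng_seed=seed,
            sigma_cell=sigma_cell,
            sigma_pack=sigma_pack,
        )

    # -- expectations ----------------------------------------------------
    def _element_effects(self, effects: Mapping[str, float]) -> np.ndarray:
        e = np.zeros(len(self.library))
        for i, el in enumerate(self.library.elements):
            if el.gene is not None and el.gene in effects:
                e[i] = effects[el.gene]
        return e

    def expected_proportions(self, sample: str) -> np.ndarray:
        """Expected read proportions per element in the named sample."""
        genotype, compartment, timepoint = _parse_sample(sample)
        w = self.cellular_abundance.copy()
        if compartment == "EV":
            w = w * self.packaging_bias
            if genotype == "Cas9":
                e = self._element_effects(self.gene_effects)
                w = w * np.power(2.0, self.guide_efficacy * e)
        else:
            if genotype == "Cas9" and timepoint not in (None, 0):
                g = self._element_effects(self.growth_effects)
                w = w * np.power(2.0, self.guide_efficacy * g)
        return w / w.sum()

    def default_samples(self, n_replicates: int = 2,
                        include_cells: bool = True) -> list[str]:
        samples = []
        for r in range(1, n_replicates + 1):
            samples += [f"WT_EV_rep{r}", f"Cas9_EV_rep{r}"]
            if include_cells:
                samples += [f"WT_cells_rep{r}", f"Cas9_cells_t0_rep{r}",
                            f"Cas9_cells_t48_rep{r}"]
        return samples

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for i, el in enumerate(self.library.elements):
            rows.append({
                "element_id": el.element_id, "gene": el.gene,
                "category": el.category,
                "ev_effect": self.gene_effects.get(el.gene, 0.0) if el.gene else 0.0,
                "growth_effect": self.growth_effects.get(el.gene, 0.0) if el.gene else 0.0,
                "efficacy": self.guide_efficacy[i],
                "cellular_abundance": self.cellular_abundance[i],
                "packaging_bias": self.packaging_bias[i],
            })
        return pd.DataFrame(rows).set_index("element_id")


@dataclass
class GroundTruth:
    """Expected proportions, planted effects and (optionally) read origins."""

    proportions: pd.DataFrame
    effects: pd.DataFrame
    read_counts: pd.DataFrame | None = None


def simulate_screen(sim: ScreenSimulation, samples: Sequence[str] | None = None,
                    n_replicates: int = 2,
                    include_cells: bool = True) -> tuple[CountMatrix, GroundTruth]:
    """Draw multinomial counts at the configured depth for every sample."""
    if sim.depth <= 0:
        raise EvscreenError("depth must be positive")
    samples = list(samples) if samples is not None else sim.default_samples(
        n_replicates, include_cells)
    rng = np.random.default_rng(np.random.SeedSequence([sim.rng_seed, 0x636e74]))
    cols, props = {}, {}
    ids = sim.library.element_ids
    for s in samples:
        p = sim.expected_proportions(s)
        props[s] = p
        cols[s] = rng.multinomial(sim.depth, p)
    counts = CountMatrix(pd.DataFrame(cols, index=ids))
    truth = GroundTruth(
        proportions=pd.DataFrame(props, index=ids),
        effects=sim.truth_table(),
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Read-level simulation
# ---------------------------------------------------------------------------

def _inject_errors(seqs: list[str], error_rate: float,
                   rng: np.random.Generator) -> list[str]:
    if error_rate <= 0 or not seqs:
        return seqs
    out = []
    for s in seqs:
        mask = rng.random(len(s)) < error_rate
        if not mask.any():
            out.append(s)
            continue
        chars = list(s)
        for j in np.flatnonzero(mask):
            chars[j] = BASES[(BASES.index(chars[j]) + rng.integers(1, 4)) % 4]
        out.append("".join(chars))
    return out


def simulate_reads(sim: ScreenSimulation, sample: str, n_reads: int,
                   error_rate: float | None = None, path=None,
                   adapter: str = DEFAULT_RNA_ADAPTER,
                   anchor: str = DEFAULT_SGRNA_ANCHOR,
                   read_length: int = 36) -> tuple[list[tuple[str, str, str]], pd.Series]:
    """Emit reads for one sample plus the true per-element read counts.

    EV samples yield mature bEXOmiR reads (barcode + EXO motif + 3' adapter
    tail, truncated to ``read_length``); cellular samples yield genomic
    sgRNA reads (anchor + protospacer). Per-base substitution errors are
    applied at ``error_rate`` (defaults to the simulation's). When ``path``
    is given the reads are also written as FASTQ (gzipped for ``.gz``).
    """
    if n_reads < 0:
        raise EvscreenError("n_reads must be >= 0")
    genotype, compartment, _ = _parse_sample(sample)
    err = sim.error_rate if error_rate is None else error_rate
    rng = np.random.default_rng(
        np.random.SeedSequence([sim.rng_seed, 0x72647321,
                                zlib.crc32(sample.encode()) % (2**31)]))
    p = sim.expected_proportions(sample)
    ids = sim.library.element_ids
    per_element = rng.multinomial(n_reads, p) if n_reads else np.zeros(len(p), int)
    truth = pd.Series(per_element, index=ids, name="true_count")

    templates = []
    for i, el in enumerate(sim.library.elements):
        if compartment == "EV":
            t = (el.barcode_seq + EXO_MOTIF + adapter)[:read_length]
        else:
            t = (anchor + el.sgrna_seq + adapter)[:read_length]
        templates.append(t)

    order = np.repeat(np.arange(len(ids)), per_element)
    rng.shuffle(order)
    seqs = _inject_errors([templates[i] for i in order], err, rng)
    records = [
        (f"{sample}:{r}:{ids[order[r]]}", seqs[r], "I" * len(seqs[r]))
        for r in range(len(order))
    ]
    if path is not None:
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(str(path), "wt") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    return records, truth


# ---------------------------------------------------------------------------
# Bias calibration
# ---------------------------------------------------------------------------

def cell_ev_r2(library: Library, sigma_pack: float, sigma_cell: float = 1.0,
               depth: int | None = None, seed: int = 0) -> float:
    """Simulated WT cell-vs-EV log2-count R^2 at one packaging-bias level."""
    sim = ScreenSimulation.create(library, sigma_cell=sigma_cell,
                                  sigma_pack=sigma_pack, depth=depth, seed=seed)
    counts, _ = simulate_screen(sim, samples=["WT_cells_rep1", "WT_EV_rep1"])
    return qc_concordance(counts, "WT_cells_rep1", "WT_EV_rep1")


def tune_bias(library: Library, target_r2: tuple[float, float] = (0.13, 0.17),
              sigma_cell: float = 1.0, depth: int | None = None, seed: int = 0,
              sigma_hi: float = 16.0, max_iter: int = 40) -> tuple[float, float]:
    """Find sigma_pack putting the cell-vs-EV R^2 inside ``target_r2``.

    R^2 decreases monotonically in sigma_pack (no bias -> near-perfect
    correlation; huge bias -> none), so a bisection on sigma_pack suffices.
    Returns (sigma_pack, achieved R^2); raises :class:`FeasibilityError`
    with the achievable bounds when the band cannot be reached.
    """
    lo_t, hi_t = target_r2
    if not (0.0 < lo_t < hi_t < 1.0):
        raise EvscreenError("target_r2 must be an increasing pair inside (0, 1)")
    mid_t = 0.5 * (lo_t + hi_t)

    r2_lo = cell_ev_r2(library, 0.0, sigma_cell, depth, seed)
    r2_hi = cell_ev_r2(library, sigma_hi, sigma_cell, depth, seed)
    if r2_lo < lo_t or r2_hi > hi_t:
        raise FeasibilityError(
            f"target R^2 {target_r2} unattainable: achievable range "
            f"[{r2_hi:.3f}, {r2_lo:.3f}] at this depth")
    lo, hi = 0.0, sigma_hi
    best = (lo, r2_lo)
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        r2 = cell_ev_r2(library, mid, sigma_cell, depth, seed)
        best = (mid, r2)
        if lo_t <= r2 <= hi_t:
            break
        if r2 > mid_t:
            lo = mid
        else:
            hi = mid
    sigma, r2 = best
    if not (lo_t <= r2 <= hi_t):
        raise FeasibilityError(f"bisection ended outside the band: R^2={r2:.3f}")
    return sigma, r2
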