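"""Numeric toolkit for orthogonal miRNA-profiling validation assays.

Covers the arithmetic of nCounter-style miRNA panels — geometric-mean
normalization of cellular fractions, spike-in normalization of EV
fractions, a signal-to-noise detection filter against negative-control
probes, percent-of-control summaries of knockout versus control samples —
plus relative qPCR quantitation by the delta-Ct method.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import EvscreenError


@dataclass
class ProfileMatrix:
    """miRNA x sample count matrix with optional probe annotations.

    ``fractions`` labels each sample "cellular" or "EV"; ``negatives``
    names negative-control probe rows; ``spike_id`` names the synthetic
    spike-in oligo row used for EV normalization.
    """

    data: pd.DataFrame
    fractions: dict[str, str] = field(default_factory=dict)
    negatives: list[str] = field(default_factory=list)
    spike_id: str | None = None

    def __post_init__(self) -> None:
        if (self.data.to_numpy() < 0).any():
            raise EvscreenError("profile counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def samples_of(self, fraction: str) -> list[str]:
        if not self.fractions:
            return self.samples
        return [s for s in self.samples if self.fractions.get(s) == fraction]

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        cat = pd.Series("endogenous", index=df.index, name="category")
        cat.loc[cat.index.isin(self.negatives)] = "negative"
        if self.spike_id is not None and self.spike_id in cat.index:
            cat.loc[self.spike_id] = "spike"
        out = pd.concat([cat, df], axis=1)
        out.index.name = "mirna_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, fractions: dict[str, str] | None = None) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="mirna_id")
        negatives: list[str] = []
        spike = None
        if "category" in df.columns:
            cat = df.pop("category")
            negatives = list(cat.index[cat == "negative"])
            spikes = list(cat.index[cat == "spike"])
            spike = spikes[0] if spikes else None
        return cls(df.astype(float), fractions=fractions or {},
                   negatives=negatives, spike_id=spike)


def _geometric_mean(values: np.ndarray) -> float:
    return float(np.exp(np.mean(np.log(values))))


def normalize_cellular(pm: ProfileMatrix, top_n: int = 100) -> ProfileMatrix:
    """Normalize each sample by the geometric mean of its top-N miRNAs.

    The per-sample factor is the geometric mean of its ``top_n`` highest
    raw counts; counts are rescaled by (mean factor across samples) /
    (sample factor). Zeros among the top-N trigger a +1 offset inside the
    geometric mean (skipped otherwise, keeping the transform exactly
    scale-invariant and idempotent on positive data).
    """
    df = pm.data.astype(float)
    factors = {}
    for s in df.columns:
        col = df[s].to_numpy()
        if np.count_nonzero(col) < top_n:
            raise EvscreenError(f"sample {s}: fewer than top_n={top_n} nonzero miRNAs")
        top = np.sort(col)[-top_n:]
        if (top == 0).any():
            top = top + 1.0
        factors[s] = _geometric_mean(top)
    mean_factor = float(np.mean(list(factors.values())))
    out = df.copy()
    for s in df.columns:
        out[s] = df[s] * (mean_factor / factors[s])
    return replace(pm, data=out)


def normalize_ev(pm: ProfileMatrix, spike_id: str | None = None) -> ProfileMatrix:
    """Normalize EV samples by the synthetic spike-in oligo.

    Each EV sample is divided by its spike count and rescaled to the mean
    spike level, so the spike row is constant afterwards. Non-EV samples
    pass through untouched.
    """
    spike = spike_id or pm.spike_id
    if spike is None or spike not in pm.data.index:
        raise EvscreenError("spike_id missing from the profile matrix")
    ev_samples = pm.samples_of("EV")
    if not ev_samples:
        raise EvscreenError("no EV samples to normalize")
    spikes = pm.data.loc[spike, ev_samples].astype(float)
    if (spikes <= 0).any():
        raise EvscreenError("zero spike count in an EV sample")
    mean_spike = float(spikes.mean())
    out = pm.data.astype(float).copy()
    for s in ev_samples:
        out[s] = out[s] * (mean_spike / spikes[s])
    return replace(pm, data=out, spike_id=spike)


def detection_filter(pm: ProfileMatrix, negatives: Sequence[str] | None = None,
                     n_sd: float = 2.0) -> ProfileMatrix:
    """Keep miRNAs consistently above background in every sample.

    Background per sample is mean + ``n_sd`` * SD of that sample's
    negative-control probes; a miRNA survives only if it exceeds the
    threshold in all samples of its fraction (all samples when no fraction
    labels exist). Negative probes themselves are removed from the output.
    """
    negs = list(negatives) if negatives is not None else pm.negatives
    if not negs:
        raise EvscreenError("no negative-control probes identified")
    missing = [n for n in negs if n not in pm.data.index]
    if missing:
        raise EvscreenError(f"negative probes absent from matrix: {missing}")
    neg = pm.data.loc[negs].astype(float)
    thresh = neg.mean(axis=0) + n_sd * neg.std(axis=0, ddof=1)
    body = pm.data.drop(index=negs)
    if pm.spike_id in body.index:
        body = body.drop(index=pm.spike_id)
    fractions = set(pm.fractions.values()) or {None}
    keep = pd.Series(False, index=body.index)
    for frac in fractions:
        samples = pm.samples_of(frac) if frac is not None else pm.samples
        if not samples:
            continue
        above = (body[samples] > thresh[samples]).all(axis=1)
        keep |= above
    out = body.loc[keep]
    return replace(pm, data=out, negatives=[])


def percent_of_control(ko: ProfileMatrix, ctrl: ProfileMatrix) -> pd.DataFrame:
    """Knockout counts as percent of control, per shared miRNA and experiment.

    Sample columns are paired positionally (experiment 1 with experiment 1,
    ...). miRNAs with a zero control count in any experiment are flagged
    (``excluded`` column) and carry NaN percentages there. A ``mean``
    column averages across experiments.
    """
    shared = ko.data.index.intersection(ctrl.data.index)
    if shared.empty:
        raise EvscreenError("no shared miRNA ids")
    if len(ko.samples) != len(ctrl.samples):
        raise EvscreenError("ko and control must have the same number of experiments")
    out = {}
    excluded = pd.Series(False, index=shared)
    for i, (ks, cs) in enumerate(zip(ko.samples, ctrl.samples), start=1):
        c = ctrl.data.loc[shared, cs].astype(float)
        k = ko.data.loc[shared, ks].astype(float)
        zero = c == 0
        excluded |= zero
        pct = 100.0 * k / c.where(~zero)
        out[f"exp{i}"] = pct
    df = pd.DataFrame(out, index=shared)
    df["mean"] = df.mean(axis=1)
    df["excluded"] = excluded
    return df


def delta_ct(ct_target: float | np.ndarray, ct_reference: float | np.ndarray):
    """Relative transcript level 2^-(Ct_target - Ct_reference)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference).all()):
        raise EvscreenError("Ct values must be finite")
    out = np.power(2.0, -(ct_target - ct_reference))
    return float(out) if out.ndim == 0 else out
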