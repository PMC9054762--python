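"""Threshold prevalence over IDR sets and random-subset proteome nulls.

Prevalence is the fraction of IDRs whose maximum stretch score is strictly
greater than a threshold (default thresholds 1.5, 2.0, 2.5), or that contain
a qualifying helix element. The null model draws k random subsets of
proteins (without replacement within a draw, independently across draws)
from a reference proteome, pools their IDRs, and records the statistic's
distribution, mean and sample standard deviation — the negative control an
observed protein set (e.g. RNA-binding proteins) is compared against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (1.5, 2.0, 2.5)

#: Subset sizes used for the reference resampling controls: the sizes of the
#: curated RNA-binding protein census (1542) and its mRNA-binding subset
#: (689 as used for resampling; the census text also quotes 692).
RBP_SUBSET_SIZE = 1542
MRBP_SUBSET_SIZE = 689


@dataclass
class PrevalenceReport:
    """Per-threshold counts/fractions of scored IDRs for one protein set.

    ``fractions`` values are None (flagged undefined) when the set holds no
    IDRs, never silently 0.
    """

    set_label: str
    n_proteins: int
    n_idrs: int
    thresholds: tuple[float, ...]
    counts: dict[float, int]
    fractions: dict[float, float | None]
    helix_element_count: int | None = None
    helix_element_fraction: float | None = None

    def __post_init__(self) -> None:
        lower = None
        for t in sorted(self.thresholds):
            f = self.fractions[t]
            if f is not None:
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction at threshold {t} outside [0,1]")
                if lower is not None and f > lower + 1e-12:
                    raise ValueError("prevalence must be non-increasing in threshold")
                lower = f

    def to_dict(self) -> dict:
        return {
            "set_label": self.set_label,
            "n_proteins": self.n_proteins,
            "n_idrs": self.n_idrs,
            "thresholds": list(self.thresholds),
            "counts": {str(t): c for t, c in self.counts.items()},
            "fractions": {str(t): f for t, f in self.fractions.items()},
            "helix_element_count": self.helix_element_count,
            "helix_element_fraction": self.helix_element_fraction,
        }


def prevalence(
    scored: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    set_label: str = "",
) -> PrevalenceReport:
    """Prevalence of IDRs scoring strictly above each threshold.

    ``scored`` is a per-IDR table as produced by
    :func:`idrhelix.scoring.score_segments` (columns ``accession``,
    ``max_score`` and optionally ``has_helix_element``).
    """
    n_idrs = len(scored)
    n_proteins = scored["accession"].nunique() if n_idrs else 0
    counts: dict[float, int] = {}
    fractions: dict[float, float | None] = {}
    for t in thresholds:
        c = int((scored["max_score"] > t).sum()) if n_idrs else 0
        counts[float(t)] = c
        fractions[float(t)] = (c / n_idrs) if n_idrs else None
    helix_count = helix_frac = None
    if n_idrs and "has_helix_element" in scored and scored["has_helix_element"].notna().all():
        helix_count = int(scored["has_helix_element"].astype(bool).sum())
        helix_frac = helix_count / n_idrs
    return PrevalenceReport(
        set_label=set_label,
        n_proteins=n_proteins,
        n_idrs=n_idrs,
        thresholds=tuple(float(t) for t in thresholds),
        counts=counts,
        fractions=fractions,
        helix_element_count=helix_count,
        helix_element_fraction=helix_frac,
    )


# ---------------------------------------------------------------------------
# Statistics over protein subsets

Statistic = Callable[[pd.DataFrame, int], float]
"""A prevalence functional: (pooled IDR table of the subset, n proteins) -> value."""


def idr_prevalence_statistic(threshold: float) -> Statistic:
    """Fraction of the subset's IDRs scoring strictly above ``threshold``."""

    def stat(idrs: pd.DataFrame, n_proteins: int) -> float:
        if len(idrs) == 0:
            return float("nan")
        return float((idrs["max_score"] > threshold).mean())

    stat.__name__ = f"idr_prevalence_gt_{threshold}"
    return stat


def protein_prevalence_statistic(threshold: float) -> Statistic:
    """Fraction of subset proteins owning at least one IDR above threshold."""

    def stat(idrs: pd.DataFrame, n_proteins: int) -> float:
        if n_proteins == 0:
            return float("nan")
        passing = idrs.loc[idrs["max_score"] > threshold, "accession"].nunique()
        return passing / n_proteins

    stat.__name__ = f"protein_prevalence_gt_{threshold}"
    return stat


def helix_element_statistic() -> Statistic:
    """Fraction of the subset's IDRs containing a helix element."""

    def stat(idrs: pd.DataFrame, n_proteins: int) -> float:
        if len(idrs) == 0:
            return float("nan")
        return float(idrs["has_helix_element"].astype(bool).mean())

    stat.__name__ = "idr_helix_element_prevalence"
    return stat


@dataclass
class NullDistribution:
    """Statistic values over k random protein subsets of a proteome."""

    statistic_name: str
    subset_size: int
    k: int
    seed: int
    values: np.ndarray
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != self.k:
            raise ValueError("values length must equal k")
        self.mean = float(self.values.mean())
        # sample SD (k-1 denominator): error bars over the k draws;
        # exactly 0 when all draws coincide (avoids rounding residue)
        if self.k <= 1 or np.ptp(self.values) == 0.0:
            self.sd = 0.0
        else:
            self.sd = float(self.values.std(ddof=1))

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "subset_size": self.subset_size,
            "k": self.k,
            "seed": self.seed,
            "mean": self.mean,
            "sd": self.sd,
            "values": self.values.tolist(),
        }


def resample_null(
    accessions: Sequence[str],
    scored_idrs: pd.DataFrame,
    subset_size: int,
    statistic: Statistic,
    k: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of ``statistic`` over ``k`` random protein subsets.

    ``accessions`` is the full reference population (proteins without IDRs
    included — they dilute protein-level statistics exactly as in the real
    proteome). Each draw samples ``subset_size`` proteins without
    replacement; draws are independent. Fully reproducible from ``seed``.
    """
    accessions = np.asarray(accessions, dtype=object)
    if subset_size > accessions.size:
        raise ValueError(
            f"subset_size {subset_size} exceeds population size {accessions.size}"
        )
    # row positions per accession: pooling a subset's IDRs is then one take()
    positions: dict[str, np.ndarray] = {
        acc: np.asarray(idx, dtype=np.intp)
        for acc, idx in scored_idrs.groupby("accession", sort=False).indices.items()
    }
    empty = np.empty(0, dtype=np.intp)
    rng = np.random.default_rng(seed)
    values = np.empty(k, dtype=float)
    for i in range(k):
        chosen = rng.choice(accessions, size=subset_size, replace=False)
        rows = [positions[a] for a in chosen if a in positions]
        pooled = scored_idrs.take(np.concatenate(rows) if rows else empty)
        values[i] = statistic(pooled, subset_size)
    return NullDistribution(
        statistic_name=getattr(statistic, "__name__", "statistic"),
        subset_size=int(subset_size),
        k=int(k),
        seed=int(seed),
        values=values,
    )


@dataclass(frozen=True)
class NullComparison:
    """Displacement of an observed value from a resampling null."""

    observed: float
    displacement: float  # (observed - null mean) / null SD
    quantile: float      # empirical: fraction of null values <= observed
    degenerate: bool     # True when the null SD is zero


def compare_to_null(observed: float | PrevalenceReport, null: NullDistribution,
                    threshold: float | None = None) -> NullComparison:
    """Z-like displacement and empirical quantile of ``observed`` in the null.

    ``observed`` may be a raw value or a :class:`PrevalenceReport` together
    with the threshold whose fraction should be compared.
    """
    if isinstance(observed, PrevalenceReport):
        if threshold is None:
            raise ValueError("pass the threshold to extract from the report")
        value = observed.fractions[float(threshold)]
        if value is None:
            raise ValueError("observed report has no IDRs; fraction undefined")
    else:
        value = float(observed)
    if null.sd == 0.0:
        diff = value - null.mean
        disp = 0.0 if np.isclose(value, null.mean) else float(np.copysign(np.inf, diff))
        degenerate = True
    else:
        disp = (value - null.mean) / null.sd
        degenerate = False
    quant = float((null.values <= value).mean())
    return NullComparison(value, float(disp), quant, degenerate)


def write_report_json(
    path: str | Path,
    report: PrevalenceReport,
    nulls: Sequence[NullDistribution] = (),
    comparisons: dict[str, NullComparison] | None = None,
) -> None:
    doc = {
        "report": report.to_dict(),
        "nulls": [n.to_dict() for n in nulls],
        "comparisons": {
            name: {
                "observed": c.observed,
                "displacement": c.displacement,
                "quantile": c.quantile,
                "degenerate": c.degenerate,
            }
            for name, c in (comparisons or {}).items()
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))
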