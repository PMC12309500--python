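"""Core domain containers for the myonuclear chromatin-dynamics pipeline.

The study design is a 2 (training state) x 3 (time post-exercise) grid of
exercised groups plus a sedentary baseline.  Every condition label used across
the package is of the form ``"<state>_<time>"`` (e.g. ``"untrained_6h"``) with
the baseline labelled ``"sedentary"``.

Coordinate convention: all genomic intervals are 0-based half-open (BED).  For
minus-strand genes the TSS coordinate equals the gene-body *end* (the exclusive
bound), i.e. the 5' end of a minus-strand feature is its ``end`` — the usual
BED convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

STATES: tuple[str, ...] = ("untrained", "trained")
TIMES: tuple[str, ...] = ("0h", "6h", "72h")
SEDENTARY = "sedentary"

#: the six exercised conditions, in canonical order
CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    (state, time) for state in STATES for time in TIMES
)


def condition_label(state: str, time: str | None = None) -> str:
    """Canonical label for a (state, time) pair; sedentary has no time."""
    if state == SEDENTARY:
        return SEDENTARY
    if time not in TIMES:
        raise ValueError(f"unknown time point {time!r}")
    if state not in STATES:
        raise ValueError(f"unknown training state {state!r}")
    return f"{state}_{time}"


CONDITION_LABELS: tuple[str, ...] = tuple(condition_label(s, t) for s, t in CONDITIONS)


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES and feature intervals.

    ``exons``, ``utr5`` and ``utr3`` are tuples of half-open ``(start, end)``
    intervals lying inside the gene body.  For a plus-strand gene
    ``tss < tes`` and the body is ``[tss, tes)``; for a minus-strand gene
    ``tss > tes`` and the body is ``[tes, tss)``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: plus-strand gene needs tss < tes")
        if self.strand == "-" and not self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: minus-strand gene needs tss > tes")
        lo, hi = self.start, self.end
        for name in ("exons", "utr5", "utr3"):
            for s, e in getattr(self, name):
                if not (lo <= s < e <= hi):
                    raise ValueError(
                        f"{self.gene_id}: {name} interval ({s},{e}) outside body [{lo},{hi})"
                    )
        if not self.exons:
            raise ValueError(f"{self.gene_id}: at least one exon required")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)


@dataclass(frozen=True)
class PeakRecord:
    """An accessible region (0-based half-open)."""

    chrom: str
    start: int
    end: int
    peak_id: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.peak_id}: need 0 <= start < end")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class EffectSpec:
    """Planted effect structure for the synthetic generator.

    Defaults encode the study conditions the pipeline targets: an
    overrepresentation of chromatin closing at 0 h that training amplifies
    ~1.4-fold, an untrained accessibility gain peaking at 6 h of which ~55%
    arises de novo, a reversal subset (gained in untrained / lost in trained
    at 0 h), longer survival of planted effects in the trained state, and a
    myonuclear-responsive gene subset (~23% of genes).
    """

    frac_loss_0h_untrained: float = 0.10
    amplification_trained: float = 1.4
    frac_gain_6h_untrained: float = 0.07
    frac_de_novo_6h: float = 0.55
    #: per-state (survive 0h->6h, survive 6h->72h) probabilities for losses
    retention_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"untrained": (0.5, 0.0), "trained": (0.75, 0.6)}
    )
    reversal_frac: float = 0.76
    lfc_magnitude: float = 2.0
    dispersion: float = 0.05
    n_per_group: int = 3
    myonuclear_frac: float = 0.23

    def __post_init__(self) -> None:
        fracs = {
            "frac_loss_0h_untrained": self.frac_loss_0h_untrained,
            "frac_gain_6h_untrained": self.frac_gain_6h_untrained,
            "frac_de_novo_6h": self.frac_de_novo_6h,
            "reversal_frac": self.reversal_frac,
            "myonuclear_frac": self.myonuclear_frac,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for state, (p1, p2) in self.retention_profile.items():
            if state not in STATES:
                raise ValueError(f"retention_profile: unknown state {state!r}")
            if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
                raise ValueError("retention probabilities must lie in [0, 1]")
        if self.amplification_trained < 1.0:
            raise ValueError("amplification_trained must be >= 1")
        if self.lfc_magnitude <= 0:
            raise ValueError("lfc_magnitude must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


@dataclass
class CountMatrix:
    """Peak x sample fragment counts plus the sample design.

    ``counts`` is a peaks x samples integer DataFrame; ``design`` is indexed
    by sample id with columns ``state`` and ``time`` (time ``"NA"`` for
    sedentary).
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if c.size and (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.size and not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integral")
        missing = set(self.counts.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples missing from design: {sorted(missing)}")
        if not (self.design.loc[list(self.counts.columns), "state"] == SEDENTARY).any():
            raise ValueError("design must contain a non-empty sedentary group")

    def samples_of(self, state: str, time: str | None = None) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        d = self.design.loc[list(self.counts.columns)]
        if state == SEDENTARY:
            mask = d["state"] == SEDENTARY
        else:
            mask = (d["state"] == state) & (d["time"] == time)
        return list(d.index[mask])

    @property
    def peak_ids(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generator, for parameter-recovery tests.

    ``directions`` is a peaks x conditions DataFrame over
    ``{"gain", "loss", "none"}`` (total: every peak x condition has exactly
    one entry).  ``peak_gene`` maps each peak to its nearest gene as assigned
    at generation time.  ``atac_lib_factors`` are the true per-sample library
    scaling factors used when drawing counts.
    """

    directions: pd.DataFrame
    myonuclear_genes: frozenset[str]
    peak_gene: pd.Series
    atac_lib_factors: pd.Series | None = None
    rna_lib_factors: pd.Series | None = None
    expression_lfc: pd.DataFrame | None = None
    motif_activity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        bad = set(np.unique(self.directions.to_numpy())) - {"gain", "loss", "none"}
        if bad:
            raise ValueError(f"invalid planted directions: {sorted(bad)}")
        if list(self.directions.columns) != list(CONDITION_LABELS):
            raise ValueError("truth must cover every exercised condition")

    def planted_set(self, state: str, time: str, direction: str) -> set[str]:
        col = self.directions[condition_label(state, time)]
        return set(col.index[col == direction])
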