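"""Temporal set algebra over differential-accessibility calls.

Direction sets key gene ids (or, optionally, region ids) by
(state, time, direction).  On top of them the module computes pairwise
overlaps, the trained-vs-untrained excess, the reversal analysis
(gained-in-one-state / lost-in-the-other), the de-novo emergence fraction at
later time points, and the retention taxonomy comparing how long a gene's
differential status persists in each training state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .models import STATES, TIMES

DirectionSetTable = dict[tuple[str, str, str], set[str]]


def build_direction_sets(
    diff: dict[str, pd.DataFrame],
    annotations: pd.DataFrame | None = None,
    *,
    level: str = "gene",
) -> DirectionSetTable:
    """Gene- (default) or region-level direction sets per condition.

    ``diff`` maps condition labels (``"<state>_<time>"``) to result tables
    carrying ``direction``.  At gene level every differential peak must be
    present in ``annotations`` (indexed by peak_id with a ``gene_id``
    column); a missing annotation raises.  A gene enters (state, time, gain)
    if at least one of its peaks is called gain there, and may legitimately
    sit in both direction sets of one condition.
    """
    if level not in ("gene", "region"):
        raise ValueError("level must be 'gene' or 'region'")
    if level == "gene" and annotations is None:
        raise ValueError("gene-level sets require peak annotations")
    table: DirectionSetTable = {}
    for label, df in diff.items():
        state, time = label.rsplit("_", 1)
        for direction in ("gain", "loss"):
            ids = df.index[df["direction"] == direction]
            if level == "region":
                members = set(ids)
            else:
                missing = [pid for pid in ids if pid not in annotations.index]
                if missing:
                    raise ValueError(
                        f"{len(missing)} differential peaks lack annotations "
                        f"(first: {missing[0]!r})"
                    )
                members = set(annotations.loc[list(ids), "gene_id"])
            table[(state, time, direction)] = members
    return table


def venn_overlap(set_a: set[str], set_b: set[str]) -> tuple[int, int, int, float]:
    """(|a only|, |a & b|, |b only|, |a & b| / |a|); fraction 0 with a warning
    when a is empty."""
    inter = set_a & set_b
    if set_a:
        frac = len(inter) / len(set_a)
    else:
        warnings.warn("venn_overlap: first set is empty, fraction reported as 0")
        frac = 0.0
    return len(set_a - set_b), len(inter), len(set_b - set_a), frac


def excess_count(trained_set: set[str] | int, untrained_set: set[str] | int) -> int:
    """Signed difference of cardinalities, |trained| - |untrained|.

    Accepts sets or plain cardinalities (useful when only published set
    sizes are available).
    """
    nt = trained_set if isinstance(trained_set, int) else len(trained_set)
    nu = untrained_set if isinstance(untrained_set, int) else len(untrained_set)
    return nt - nu


def reversal_analysis(
    gain_set: set[str], loss_set: set[str]
) -> tuple[int, float, float]:
    """Overlap of genes gained in one state with genes lost in the other.

    Returns (overlap count, overlap/|gain|, overlap/|loss|).  An empty gain
    set leaves the fraction undefined and raises.
    """
    if not gain_set:
        raise ValueError("reversal fraction undefined for an empty gain set")
    overlap = len(gain_set & loss_set)
    share = overlap / len(loss_set) if loss_set else 0.0
    return overlap, overlap / len(gain_set), share


def de_novo_fraction(
    table: DirectionSetTable, state: str, direction: str, time: str
) -> float:
    """Fraction of the (state, direction) set at ``time`` absent from all
    earlier post-exercise time points."""
    if time not in ("6h", "72h"):
        raise ValueError("de-novo fraction is defined for 6h and 72h only")
    earlier = {"6h": ("0h",), "72h": ("0h", "6h")}[time]
    current = table.get((state, time, direction), set())
    if not current:
        raise ValueError(f"empty set for ({state}, {time}, {direction})")
    seen: set[str] = set()
    for t in earlier:
        seen |= table.get((state, t, direction), set())
    return len(current - seen) / len(current)


@dataclass(frozen=True)
class RetentionClass:
    gene_id: str
    untrained_pattern: frozenset[str]
    trained_pattern: frozenset[str]
    label: str


def _retention_length(pattern: frozenset[str]) -> int:
    """Length of the maximal prefix chain 0h -> 6h -> 72h.

    A gene appearing only at later time points keeps its raw pattern size.
    """
    if not pattern:
        return 0
    if "0h" not in pattern:
        return len(pattern)
    n = 1
    if "6h" in pattern:
        n = 2
        if "72h" in pattern:
            n = 3
    return n


def retention_label(untrained: frozenset[str], trained: frozenset[str]) -> str:
    """Deterministic label for one (untrained, trained) membership pair."""
    if not untrained and not trained:
        return "absent"
    lu, lt = _retention_length(untrained), _retention_length(trained)
    if lt > lu:
        return "trained_longer"
    if lt < lu:
        return "untrained_longer"
    return "equal"


def classify_retention(table: DirectionSetTable, direction: str) -> list[RetentionClass]:
    """Retention taxonomy over every gene seen in either state.

    Output is a partition: exactly one record per gene in the union of all
    (state, time, direction) sets for the given direction.
    """
    genes: set[str] = set()
    for state in STATES:
        for time in TIMES:
            genes |= table.get((state, time, direction), set())
    out = []
    for gene in sorted(genes):
        u = frozenset(
            t for t in TIMES if gene in table.get(("untrained", t, direction), set())
        )
        t = frozenset(
            tt for tt in TIMES if gene in table.get(("trained", tt, direction), set())
        )
        out.append(RetentionClass(gene, u, t, retention_label(u, t)))
    return out


def retention_summary(classes: list[RetentionClass]) -> pd.DataFrame:
    """Count genes per (untrained_pattern, trained_pattern, label) cell."""
    rows = [
        (
            "+".join(sorted(c.untrained_pattern, key=TIMES.index)) or "-",
            "+".join(sorted(c.trained_pattern, key=TIMES.index)) or "-",
            c.label,
        )
        for c in classes
    ]
    df = pd.DataFrame(rows, columns=["untrained_pattern", "trained_pattern", "label"])
    return (
        df.value_counts()
        .rename("n_genes")
        .reset_index()
        .sort_values("n_genes", ascending=False, ignore_index=True)
    )
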