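"""Group-mean log-TPM z-scores, hierarchical clustering, motif-target subsets.

z-scores standardize, per gene, the group means of log2(TPM + pseudocount)
across the seven (state, time) groups including sedentary.  Clustering is
plain SciPy hierarchical clustering on Euclidean distances.  The
motif-target helpers build the union of each motif's top-k target genes and
tally their per-condition accessibility associations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .dynamics import DirectionSetTable
from .models import CONDITION_LABELS, SEDENTARY, condition_label


def group_means_log_tpm(
    tpm: pd.DataFrame, design: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-gene mean of log2(TPM + pseudocount) within each sample group."""
    log_tpm = np.log2(tpm + pseudocount)
    groups: dict[str, list[str]] = {}
    for s in tpm.columns:
        state = design.loc[s, "state"]
        label = SEDENTARY if state == SEDENTARY else condition_label(state, design.loc[s, "time"])
        groups.setdefault(label, []).append(s)
    order = [SEDENTARY] + [c for c in CONDITION_LABELS if c in groups]
    if any(len(v) < 1 for v in groups.values()):
        raise ValueError("every group needs >= 1 sample")
    return pd.DataFrame({g: log_tpm[groups[g]].mean(axis=1) for g in order})


def zscore_by_group(
    tpm: pd.DataFrame,
    design: pd.DataFrame,
    gene_subset: list[str] | set[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Genes x groups z-score matrix of group-mean log2(TPM + pc).

    Each row is standardized to mean 0 / sd 1 (ddof=1) across groups;
    zero-variance genes become all-zero rows (flagged in ``attrs``).  Genes
    requested but absent from the matrix raise, listing the missing ids.
    """
    if gene_subset is not None:
        missing = sorted(set(gene_subset) - set(tpm.index))
        if missing:
            raise ValueError(f"genes absent from the TPM matrix: {missing[:10]}")
        tpm = tpm.loc[sorted(set(gene_subset))]
    means = group_means_log_tpm(tpm, design, pseudocount)
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    flat = sd == 0
    sd_safe = sd.mask(flat, 1.0)
    z = means.sub(mu, axis=0).div(sd_safe, axis=0)
    z[flat] = 0.0
    z.attrs["zero_variance_genes"] = list(z.index[flat])
    return z


def hierarchical_cluster(
    matrix: pd.DataFrame,
    metric: str = "euclidean",
    method: str = "complete",
    k: int | None = None,
) -> tuple[list[str], pd.Series | None]:
    """Hierarchical clustering of rows; returns (leaf order, labels at k).

    Deterministic for fixed input.  ``labels`` is None when ``k`` is not
    given.  Fewer than two rows raise.
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs >= 2 rows")
    dist = pdist(matrix.to_numpy(dtype=float), metric=metric)
    Z = linkage(dist, method=method)
    order = [matrix.index[i] for i in leaves_list(Z)]
    labels = None
    if k is not None:
        labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"), index=matrix.index, name="cluster")
    return order, labels


def top_targets_union(
    target_scores: dict[str, list[str]],
    k: int = 200,
    motifs_of_interest: list[str] | None = None,
) -> set[str]:
    """Union of the top-k target genes of each selected motif.

    Lists shorter than k are used whole with a warning.  Unknown motif names
    raise.
    """
    motifs = motifs_of_interest if motifs_of_interest is not None else list(target_scores)
    unknown = [m for m in motifs if m not in target_scores]
    if unknown:
        raise ValueError(f"unknown motifs: {unknown}")
    union: set[str] = set()
    for m in motifs:
        ranked = target_scores[m]
        if len(ranked) < k:
            warnings.warn(f"motif {m!r} has only {len(ranked)} ranked targets (< {k})")
        union |= set(ranked[:k])
    return union


def target_accessibility_breakdown(
    target_set: set[str], direction_sets: DirectionSetTable
) -> pd.DataFrame:
    """Per-condition gain / loss / gain_and_loss counts within a target set.

    A target gene counts as gain_and_loss in a condition when it sits in
    both direction sets of that same condition.
    """
    rows = []
    conditions = sorted({(s, t) for (s, t, _d) in direction_sets})
    for state, time in conditions:
        gains = direction_sets.get((state, time, "gain"), set()) & target_set
        losses = direction_sets.get((state, time, "loss"), set()) & target_set
        both = gains & losses
        rows.append(
            (
                condition_label(state, time),
                len(gains - both),
                len(losses - both),
                len(both),
            )
        )
    return pd.DataFrame(rows, columns=["condition", "gain", "loss", "gain_and_loss"])
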