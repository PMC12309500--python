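"""Motif-activity inference: PWM site counting + ridge decomposition.

This module is an explicit surrogate for web-service motif-activity tools:
per-peak accessibility signal is decomposed as
``signal[:, s] ~ motif_counts @ activity[:, s]`` with a ridge penalty, so
each motif receives one latent activity per sample (arbitrary units, rows
centered across samples).  Site counts come from log-odds PWM scanning of
peak sequences on both strands.  The model makes no claim of equivalence to
any specific external inference engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}
_ENC["N"] = 4
_COMPLEMENT = np.array([3, 2, 1, 0, 4])  # A<->T, C<->G, N->N


@dataclass(frozen=True)
class MotifModel:
    """A position weight matrix with background frequencies and a hit cutoff.

    ``pwm`` is 4 x width (rows A, C, G, T), every column summing to 1.
    ``threshold`` is the minimum log2-odds score for a position to count as
    a site.
    """

    motif_id: str
    pwm: tuple[tuple[float, ...], ...]
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        mat = np.asarray(self.pwm, dtype=float)
        if mat.shape[0] != 4 or mat.shape[1] < 4:
            raise ValueError("pwm must be 4 x width with width >= 4")
        if not np.allclose(mat.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("pwm columns must sum to 1")
        if not np.isclose(sum(self.background), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return len(self.pwm[0])

    def log_odds(self) -> np.ndarray:
        """5 x width log2-odds matrix; the fifth row (N) scores 0."""
        mat = np.clip(np.asarray(self.pwm, dtype=float), 1e-9, None)
        bg = np.asarray(self.background, dtype=float)[:, None]
        lo = np.log2(mat / bg)
        return np.vstack([lo, np.zeros((1, mat.shape[1]))])

    def max_score(self) -> float:
        return float(self.log_odds()[:4].max(axis=0).sum())


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer-encode a DNA string over {A, C, G, T, N} (case-insensitive)."""
    try:
        return np.array([_ENC[b] for b in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid base {exc.args[0]!r} in sequence") from None


def pwm_scan(sequence: str, motif: MotifModel) -> int:
    """Number of positions (both strands) scoring >= the motif threshold.

    N positions score as background (log-odds 0).  Sequences shorter than
    the motif width return 0 with a warning.
    """
    enc = encode_sequence(sequence)
    w = motif.width
    if enc.size < w:
        warnings.warn(
            f"sequence ({enc.size} bp) shorter than motif {motif.motif_id} ({w} bp)"
        )
        return 0
    lo = motif.log_odds()
    # reverse-complement scan == scanning the forward strand with the
    # base-complemented, position-reversed matrix
    lo_rc = lo[_COMPLEMENT][:, ::-1]
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    cols = np.arange(w)
    fwd = lo[windows, cols].sum(axis=1)
    rev = lo_rc[windows, cols].sum(axis=1)
    return int((fwd >= motif.threshold).sum() + (rev >= motif.threshold).sum())


def scan_peak_sequences(
    sequences: dict[str, str], motifs: list[MotifModel]
) -> pd.DataFrame:
    """Peaks x motifs site-count matrix from raw peak sequences."""
    data = {
        m.motif_id: [pwm_scan(seq, m) for seq in sequences.values()] for m in motifs
    }
    return pd.DataFrame(data, index=pd.Index(sequences.keys(), name="peak_id"))


def infer_activities(
    signal: pd.DataFrame,
    motif_counts: pd.DataFrame,
    lam: float = 1.0,
    *,
    standardize: bool = True,
) -> pd.DataFrame:
    """Ridge-penalized per-sample motif activities.

    For each sample s the activities solve
    ``min_A ||signal[:, s] - C A||^2 + lam ||A||^2`` where C is the motif
    count matrix (column-standardized when ``standardize``, the default —
    the lam = 1.0 default is calibrated for that scale).  Rows of the result
    are centered across samples.  lam = 0 with a rank-deficient C raises and
    advises a positive penalty.
    """
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if list(signal.index) != list(motif_counts.index):
        raise ValueError("signal and motif_counts must share the same peak index")
    C = motif_counts.to_numpy(dtype=float)
    if standardize:
        mu = C.mean(axis=0)
        sd = C.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        C = (C - mu) / sd
    gram = C.T @ C
    if lam == 0 and np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError(
            "motif count matrix is rank-deficient; use lam > 0 for a unique solution"
        )
    A = linalg.solve(
        gram + lam * np.eye(gram.shape[0]),
        C.T @ signal.to_numpy(dtype=float),
        assume_a="pos" if lam > 0 else "sym",
    )
    A -= A.mean(axis=1, keepdims=True)
    return pd.DataFrame(A, index=motif_counts.columns, columns=signal.columns)


def rank_targets(
    motif_id: str,
    motif_counts: pd.DataFrame,
    activities: pd.DataFrame,
    peak_gene: pd.Series,
) -> pd.DataFrame:
    """Genes ranked as targets of one motif.

    A gene's score is its summed site count across peaks times the motif's
    absolute activity change (max - min across samples).  Zero-site genes
    are excluded; ties break by site count, then gene id.  Unknown motifs
    raise.
    """
    if motif_id not in motif_counts.columns:
        raise ValueError(f"unknown motif {motif_id!r}")
    if motif_id not in activities.index:
        raise ValueError(f"motif {motif_id!r} has no inferred activity")
    sites = motif_counts[motif_id]
    genes = peak_gene.loc[sites.index]
    gene_sites = sites.groupby(genes).sum()
    gene_sites = gene_sites[gene_sites > 0]
    delta = float(activities.loc[motif_id].max() - activities.loc[motif_id].min())
    df = pd.DataFrame(
        {
            "gene_id": gene_sites.index,
            "site_count": gene_sites.to_numpy(),
            "score": gene_sites.to_numpy() * abs(delta),
        }
    )
    df = df.sort_values(
        ["score", "site_count", "gene_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df


def log_accessibility_signal(
    counts: pd.DataFrame, sf: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Column-centered log2 of size-factor-normalized counts.

    The standard input for :func:`infer_activities` when starting from a raw
    fragment count matrix.
    """
    norm = counts / sf.loc[counts.columns]
    log = np.log2(norm + pseudocount)
    return log - log.mean(axis=0)
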