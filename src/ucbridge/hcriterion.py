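"""Haplotype-window breeding values and H-criterion donor selection.

The H criterion scores a candidate donor by the genome-wide sum, over
sliding haplotype windows, of the best haplotypic estimated breeding
value (HEBV) available among the recipient, its already-incorporated
donors and the candidate — an optimal-haploid-value-type measure of the
complementary favourable haplotypes a new donor would contribute after
recurrent intercrossing and selection.  Windows are 100 SNPs wide with a
20-SNP step by default and the sum is scaled by
``lambda = step / window_size`` to offset the window overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeWindows",
    "SelectionTrajectory",
    "build_windows",
    "hebv",
    "h_criterion",
    "forward_select_donors",
    "rank_donors_by_uc",
]


@dataclass
class HaplotypeWindows:
    """Sliding haplotype windows over a marker panel.

    ``indices`` lists, per window, the positions (in map order) of its
    markers; every window is contiguous within a single chromosome.
    Trailing windows shorter than ``window_size`` at a chromosome end
    are kept, truncated, so that no marker is left uninspected.
    """

    window_size: int
    step: int
    indices: list[np.ndarray] = field(default_factory=list)
    chromosomes: list = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.indices)

    @property
    def lam(self) -> float:
        """Overlap-compensating scale ``step / window_size``."""
        return self.step / self.window_size

    def incidence(self, n_markers: int) -> np.ndarray:
        """Dense 0/1 marker x window incidence matrix ``Z``."""
        z = np.zeros((n_markers, self.n_windows), dtype=np.int8)
        for h, idx in enumerate(self.indices):
            z[idx, h] = 1
        return z


def build_windows(
    gmap: pd.DataFrame, window_size: int = 100, step: int = 20
) -> HaplotypeWindows:
    """Construct sliding windows per chromosome.

    Window starts advance by ``step`` markers within each chromosome
    (windows never span a chromosome boundary); the final windows are
    truncated at the chromosome end and duplicates (possible when a
    chromosome holds fewer markers than one step) are dropped.
    """
    if step < 1 or window_size < step:
        raise ValueError("require 1 <= step <= window_size")
    chrom = gmap["chromosome"].to_numpy()
    windows = HaplotypeWindows(window_size=window_size, step=step)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        m_c = len(idx)
        prev: tuple | None = None
        for start in range(0, m_c, step):
            sel = idx[start : start + window_size]
            key = (sel[0], sel[-1])
            if key == prev:
                continue
            prev = key
            windows.indices.append(sel)
            windows.chromosomes.append(c)
    return windows


def hebv(
    genotypes: pd.DataFrame, beta_hat: np.ndarray, windows: HaplotypeWindows
) -> pd.DataFrame:
    """Haplotypic estimated breeding values, lines x windows.

    Entry (line, window) = sum over the window's markers of
    ``genotype * effect`` — the windowed slice of the line's estimated
    breeding value.  ``beta_hat`` excludes the intercept and aligns with
    the genotype columns.
    """
    beta_hat = np.asarray(beta_hat, dtype=float)
    x = genotypes.to_numpy(dtype=float)
    if x.shape[1] != beta_hat.shape[0]:
        raise ValueError("effect vector length does not match genotype columns")
    weighted = x * beta_hat[None, :]
    cols = {}
    for h, idx in enumerate(windows.indices):
        cols[h] = weighted[:, idx].sum(axis=1)
    return pd.DataFrame(cols, index=genotypes.index)


def _best_stack(hebv_df: pd.DataFrame, lines: list) -> np.ndarray:
    return hebv_df.loc[list(lines)].to_numpy().max(axis=0)


def h_criterion(
    candidate: str,
    recipient: str,
    initial_donors,
    hebv_df: pd.DataFrame,
    lam: float,
) -> float:
    """H value of a candidate donor for one recipient.

    ``H = lambda * sum_h max(HEBV_candidate, HEBV_recipient,
    max over incorporated donors)`` — the score of the best haploid
    genome assemblable from the recipient, its current donors and the
    candidate.
    """
    initial_donors = list(initial_donors)
    if candidate in initial_donors:
        raise ValueError(f"candidate {candidate!r} already incorporated")
    stack = _best_stack(hebv_df, [candidate, recipient] + initial_donors)
    return float(lam * stack.sum())


@dataclass
class SelectionTrajectory:
    """Forward-selection order of donors with the H value at each step."""

    recipient: str
    initial_donors: list
    baseline_h: float
    table: pd.DataFrame  # columns: rank, donor, h, percent_gain

    @property
    def order(self) -> list:
        return list(self.table["donor"])


def forward_select_donors(
    recipient: str,
    initial_donors,
    candidates,
    hebv_df: pd.DataFrame,
    lam: float,
) -> SelectionTrajectory:
    """Greedy forward selection of candidate donors by the H criterion.

    At each step the candidate with the highest H (ties broken
    lexicographically by donor id) joins the incorporated set; the
    procedure repeats until candidates are exhausted.  Percent gains are
    relative to the recipient + initial-donors baseline
    ``H0 = lambda * sum_h max(HEBV_recipient, max over initial donors)``.
    """
    candidates = sorted(candidates)
    if not candidates:
        raise ValueError("no candidate donors supplied")
    incorporated = list(initial_donors)
    baseline = float(lam * _best_stack(hebv_df, [recipient] + incorporated).sum())
    rows = []
    rank = 0
    while candidates:
        scores = {c: h_criterion(c, recipient, incorporated, hebv_df, lam) for c in candidates}
        best = min(scores, key=lambda c: (-scores[c], c))
        rank += 1
        gain = np.nan if baseline == 0 else 100.0 * (scores[best] - baseline) / baseline
        rows.append(
            {"rank": rank, "donor": best, "h": scores[best], "percent_gain": gain}
        )
        incorporated.append(best)
        candidates.remove(best)
    return SelectionTrajectory(
        recipient=recipient,
        initial_donors=list(initial_donors),
        baseline_h=baseline,
        table=pd.DataFrame(rows),
    )


def rank_donors_by_uc(uc_by_candidate: dict) -> pd.DataFrame:
    """Rank candidate donors by predicted usefulness criterion.

    ``uc_by_candidate`` maps donor id to its predicted UC for the
    recipient under consideration.  Returns a table sorted by
    descending UC (ties broken lexicographically), rank starting at 1 —
    the benchmark ranking reported next to the H-based order.
    """
    if not uc_by_candidate:
        raise ValueError("no candidate predictions supplied")
    items = sorted(uc_by_candidate.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(items) + 1),
            "donor": [k for k, _ in items],
            "uc": [v for _, v in items],
        }
    )
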