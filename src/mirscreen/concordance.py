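"""Replicate-screen concordance over discretized up/neutral/down states.

The *transition matrix* is a static 3x3 cross-tabulation of states
between two screens over their common (miRNA, protein) pairs.  The
overlap statistic is the fraction of up/down calls in the reference
screen that keep their sign in the other screen; neutral-neutral
agreement is deliberately excluded, since agreement on "no change" is
not a reproduced change.  Both directions (A as reference and B as
reference) are reported, as is a per-miRNA breakdown.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .screens import DiscreteScreen

__all__ = ["TransitionMatrix", "transition_matrix", "per_mirna_consistency"]

STATES = (-1, 0, 1)


@dataclass
class TransitionMatrix:
    """3x3 state counts (rows: screen A state, cols: screen B state)."""

    counts: np.ndarray           # indexed by (-1, 0, +1) x (-1, 0, +1)
    n_pairs: int
    overlap: float | None        # sign-preserved fraction, A calls as reference
    overlap_reverse: float | None  # same with B as reference

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(STATES, name="screen_a"),
                            columns=pd.Index(STATES, name="screen_b"))


def _align(a: DiscreteScreen, b: DiscreteScreen):
    mirnas = [m for m in a.mirna_ids if m in set(b.mirna_ids)]
    proteins = [p for p in a.protein_ids if p in set(b.protein_ids)]
    if not mirnas or not proteins:
        raise ValueError("screens share no miRNAs or no proteins")
    return a.subset(mirnas, proteins), b.subset(mirnas, proteins)


def _overlap(sa: np.ndarray, sb: np.ndarray) -> float | None:
    called = sa != 0
    if not called.any():
        return None
    return float((sa[called] == sb[called]).mean())


def transition_matrix(a: DiscreteScreen, b: DiscreteScreen) -> TransitionMatrix:
    """Cross-tabulate states over common pairs and compute sign-preserved overlap.

    Screens are restricted to the intersection of their miRNA and protein
    ids (order-insensitive).  ``overlap`` is
    (counts[+,+] + counts[-,-]) / pairs with a nonzero state in A, and is
    ``None`` (flagged) when A makes no calls.
    """
    sa_screen, sb_screen = _align(a, b)
    sa = sa_screen.states.ravel()
    sb = sb_screen.states.ravel()
    counts = np.zeros((3, 3), dtype=int)
    for ia, s in enumerate(STATES):
        for ib, t in enumerate(STATES):
            counts[ia, ib] = int(((sa == s) & (sb == t)).sum())
    return TransitionMatrix(
        counts=counts,
        n_pairs=sa.size,
        overlap=_overlap(sa, sb),
        overlap_reverse=_overlap(sb, sa),
    )


def per_mirna_consistency(a: DiscreteScreen, b: DiscreteScreen) -> pd.DataFrame:
    """Sign-preserved overlap per miRNA (NaN where A makes no calls).

    The mean of per-miRNA overlaps and the pooled overlap differ when
    call rates vary across miRNAs; both views are therefore emitted by
    the pipeline.
    """
    sa_screen, sb_screen = _align(a, b)
    rows = []
    for i, m in enumerate(sa_screen.mirna_ids):
        sa = sa_screen.states[i]
        sb = sb_screen.states[i]
        ov = _overlap(sa, sb)
        rows.append({
            "mirna": m,
            "n_calls": int((sa != 0).sum()),
            "overlap": np.nan if ov is None else ov,
        })
    return pd.DataFrame(rows).set_index("mirna")
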