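"""Screen normalization and three-state discretization.

Normalization convention: subtract the per-protein median of the
non-targeting control rows, then median-center each protein across
miRNAs to remove residual plate bias.  Both steps are standard practice
for mimic screens and are exposed as flags.

Discretization uses a robust z-score per protein,
``z = (x - median) / (1.4826 * MAD)``, calling +1 / -1 beyond a
configurable threshold (default 1.5).  When the MAD degenerates to zero
but the column still varies, the scaled mean absolute deviation
(1.2533 * meanAD) is used instead; a truly constant column yields no
calls.
"""

from __future__ import annotations

import numpy as np

from .screens import DiscreteScreen, ScreenMatrix

__all__ = ["normalize", "discretize", "robust_z"]

MAD_CONSISTENCY = 1.4826  # MAD -> sigma for a normal distribution
MEANAD_CONSISTENCY = 1.2533  # mean |deviation| -> sigma fallback


def normalize(
    raw: ScreenMatrix,
    control_ids: list[str],
    center: bool = True,
    drop_controls: bool = False,
) -> ScreenMatrix:
    """Control-relative normalization of a raw screen.

    Each entry becomes ``raw - median(control rows)`` for its protein;
    with ``center=True`` a per-protein median across miRNAs is then
    removed.  At least one control row must be present.
    """
    control_ids = list(control_ids)
    missing = set(control_ids) - set(raw.mirna_ids)
    if missing:
        raise ValueError(f"control ids not in screen: {sorted(missing)}")
    if not control_ids:
        raise ValueError("at least one control row is required")
    idx = {m: i for i, m in enumerate(raw.mirna_ids)}
    ctrl_rows = np.array([idx[m] for m in control_ids])
    values = raw.values - np.median(raw.values[ctrl_rows], axis=0)
    if center:
        values = values - np.median(values, axis=0)
    mirna_ids = raw.mirna_ids
    if drop_controls:
        keep = [i for i, m in enumerate(raw.mirna_ids) if m not in set(control_ids)]
        values = values[keep]
        mirna_ids = [raw.mirna_ids[i] for i in keep]
    return ScreenMatrix(mirna_ids, raw.protein_ids, values,
                        cell_line=raw.cell_line, screen_id=raw.screen_id)


def robust_z(values: np.ndarray) -> np.ndarray:
    """Columnwise robust z-scores with a meanAD fallback for MAD = 0.

    Columns with no dispersion at all return all-zero scores.
    """
    med = np.median(values, axis=0)
    dev = values - med
    mad = np.median(np.abs(dev), axis=0)
    scale = MAD_CONSISTENCY * mad
    meanad = np.mean(np.abs(dev), axis=0)
    fallback = MEANAD_CONSISTENCY * meanad
    scale = np.where(scale > 0, scale, fallback)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(scale > 0, dev / np.where(scale > 0, scale, 1.0), 0.0)
    return z


def discretize(screen: ScreenMatrix, z_threshold: float = 1.5) -> DiscreteScreen:
    """Call up/neutral/down states per (miRNA, protein) by robust z-score."""
    if not z_threshold > 0:
        raise ValueError("z_threshold must be > 0")
    z = robust_z(screen.values)
    states = np.zeros(z.shape, dtype=np.int8)
    states[z >= z_threshold] = 1
    states[z <= -z_threshold] = -1
    return DiscreteScreen(screen.mirna_ids, screen.protein_ids, states,
                          threshold=z_threshold, cell_line=screen.cell_line,
                          screen_id=screen.screen_id)
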