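"""Synthetic miRNA-mimic screen generator.

Emulates the statistical structure of a genome-wide mimic screen read out
by reverse-phase protein array, so every downstream stage of the pipeline
can be exercised and validated against a known ground truth:

* a primary screen (default 879 miRNAs x 127 antibodies) with four planted
  active clusters (sizes 79 / 153 / 115 / 150) carrying fixed signed
  protein signatures, plus one null cluster (382 miRNAs) of pure noise
  whose members have only minor effects on the measured proteins;
* a proliferation read-out linearly coupled to designated activator and
  repressor proteins;
* three secondary screens (default 154 miRNAs, 103 proteins shared with
  the primary screen) whose phosphoprotein block is drawn from planted
  sparse Gaussian graphical models with a shared core of edges plus
  mutation- and lineage-specific edges, emulating networks that partly
  overlap across cell lines.

Ground-truth labels, supports and regulator tables are always returned
alongside the data; there is no hidden state, and identical seed + config
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .screens import PathwaySet, ProliferationTable, ScreenMatrix, is_phospho

__all__ = [
    "SimulationConfig",
    "PlantedGGM",
    "SecondaryScreens",
    "simulate_primary_screen",
    "simulate_proliferation",
    "simulate_secondary_screens",
    "random_sparse_precision",
    "planted_cell_line_ggms",
    "sample_ggm",
    "default_protein_panel",
    "default_pathways",
    "cluster_signatures",
    "partial_correlations",
    "DEFAULT_ACTIVATORS",
    "DEFAULT_REPRESSORS",
    "CELL_LINES",
]

# Antibody-level panel.  The first 20 entries are the phosphoprotein block
# used for graphical-model inference; curated names keep the planted
# signatures and networks interpretable (RPPA naming conventions).
PHOSPHO_PANEL: tuple[str, ...] = (
    "AKT_pS473", "AKT_pT308", "MEK1_pS217", "MAPK_pT202", "GSK3B_pS9",
    "S6_pS235", "S6_pS240", "P70S6K_pT389", "RB_pS807", "P27_pT198",
    "EGFR_pY1068", "ERBB2_pY1248", "SRC_pY416", "STAT3_pY705", "JUN_pS73",
    "AMPK_pT172", "ACC_pS79", "PRAS40_pT246", "EIF4EBP1_pT37", "CHK1_pS345",
)

TOTAL_PANEL: tuple[str, ...] = (
    "PTEN", "NOTCH3", "CCNB1", "CDK1", "P21", "P27", "E2F1", "CCNE1",
    "TAU", "MYC", "BCL2", "BAX", "CASP7_cl", "VIM", "FN1", "ECAD",
    "BETA_CATENIN", "GATA3", "AR", "ERALPHA", "MTOR", "TSC2", "RAPTOR",
    "IGF1R", "KIT", "FOXO3", "P53", "YAP", "CLDN7", "SMAD3",
)

# Fixed signed signature templates, one per active cluster.  Cluster ids
# follow the convention that the null cluster sits third among five:
# active clusters are 1, 2, 4, 5 and the null cluster is 3.
SIGNATURE_TEMPLATES: dict[int, tuple[tuple[str, int], ...]] = {
    1: (("NOTCH3", +1), ("AKT_pS473", +1), ("AKT_pT308", +1),
        ("JUN_pS73", +1), ("PRAS40_pT246", +1), ("MYC", +1)),
    2: (("CCNB1", -1), ("CDK1", -1), ("RB_pS807", -1),
        ("E2F1", -1), ("P21", +1), ("P27", +1)),
    3: (("TAU", -1), ("VIM", -1), ("FN1", -1),
        ("ECAD", +1), ("GATA3", +1), ("AR", +1)),
    4: (("PTEN", -1), ("S6_pS235", +1), ("S6_pS240", +1),
        ("P70S6K_pT389", +1), ("MTOR", +1), ("EIF4EBP1_pT37", +1)),
}

DEFAULT_ACTIVATORS: tuple[str, ...] = ("CCNB1", "CDK1", "S6_pS235")
DEFAULT_REPRESSORS: tuple[str, ...] = ("P21", "P27", "PTEN")

# Three synthetic cell lines emulating a design in which two lines share an
# activating-pathway mutation (A, B) and two share a tissue of origin (B, C).
CELL_LINES: dict[str, dict[str, object]] = {
    "A": {"mutant": True, "tissue": "breast"},
    "B": {"mutant": True, "tissue": "ovarian"},
    "C": {"mutant": False, "tissue": "ovarian"},
}

# Core conditional-dependence edges planted in every cell line: canonical
# signaling couples (receptor pairs, kinase cascades) plus the
# MEK -> MAPK -> GSK3B <- AKT chain (an acyclic chain keeps strong partial
# correlations positive-definite; a closed triangle of strong links is not).
CORE_EDGES: tuple[tuple[str, str], ...] = (
    ("EGFR_pY1068", "ERBB2_pY1248"),
    ("MEK1_pS217", "MAPK_pT202"),
    ("AKT_pS473", "PRAS40_pT246"),
    ("AMPK_pT172", "ACC_pS79"),
    ("SRC_pY416", "STAT3_pY705"),
    ("MAPK_pT202", "GSK3B_pS9"),
    ("AKT_pT308", "GSK3B_pS9"),
    ("S6_pS235", "S6_pS240"),
)


def default_protein_panel(n_protein: int = 127) -> list[str]:
    """Antibody id panel: 20 phospho + 30 curated totals + generic fillers."""
    base = list(PHOSPHO_PANEL) + list(TOTAL_PANEL)
    if n_protein <= len(base):
        return base[:n_protein]
    fillers = [f"AB{i:03d}" for i in range(len(base) + 1, n_protein + 1)]
    return base + fillers


def default_pathways() -> list[PathwaySet]:
    """Seven overlapping pathway sets over the default panel (GMT fixture)."""
    defs = {
        "CellCycle": ("CCNB1", "CDK1", "P21", "P27", "RB_pS807", "E2F1", "CCNE1"),
        "PI3K_AKT": ("AKT_pS473", "AKT_pT308", "PTEN", "PRAS40_pT246",
                     "P70S6K_pT389", "S6_pS235", "S6_pS240"),
        "MAPK": ("MEK1_pS217", "MAPK_pT202", "JUN_pS73", "GSK3B_pS9"),
        "mTOR": ("MTOR", "TSC2", "RAPTOR", "EIF4EBP1_pT37", "P70S6K_pT389",
                 "S6_pS235"),
        "RTK": ("EGFR_pY1068", "ERBB2_pY1248", "IGF1R", "KIT", "SRC_pY416"),
        "EMT": ("VIM", "FN1", "ECAD", "BETA_CATENIN"),
        "Apoptosis": ("BCL2", "BAX", "CASP7_cl"),
    }
    return [PathwaySet(name, frozenset(members), "synthetic fixture")
            for name, members in defs.items()]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic screens.

    Defaults mirror the screen dimensions the pipeline is built for:
    879 miRNAs x 127 antibodies, active clusters of 79/153/115/150 miRNAs
    (remainder null), 6 signature proteins per cluster with mean |log2FC|
    1.0 against residual noise of SD 0.25.
    """

    n_mirna: int = 879
    n_protein: int = 127
    cluster_sizes: tuple[int, ...] = (79, 153, 115, 150)
    signature_size: int = 6
    effect_size: float = 1.0
    noise_sd: float = 0.25
    n_controls: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.cluster_sizes = tuple(int(s) for s in self.cluster_sizes)
        if self.effect_size <= 0:
            raise ValueError("effect_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if sum(self.cluster_sizes) > self.n_mirna:
            raise ValueError(
                f"cluster_sizes sum to {sum(self.cluster_sizes)} "
                f"> n_mirna = {self.n_mirna}"
            )
        if self.signature_size < 1 or self.signature_size > self.n_protein:
            raise ValueError("signature_size must be in [1, n_protein]")

    @property
    def n_null(self) -> int:
        return self.n_mirna - sum(self.cluster_sizes)

    @property
    def cluster_ids(self) -> tuple[int, ...]:
        """Active cluster ids; with 4 active clusters the null cluster is 3."""
        k = len(self.cluster_sizes)
        if k == 4:
            return (1, 2, 4, 5)
        return tuple(range(1, k + 1))

    @property
    def null_cluster_id(self) -> int:
        return 3 if len(self.cluster_sizes) == 4 else len(self.cluster_sizes) + 1


def cluster_signatures(
    config: SimulationConfig, protein_ids: Sequence[str]
) -> dict[int, dict[str, float]]:
    """Signed signature (protein -> +-effect_size) per active cluster.

    Curated templates are used where their proteins exist in the panel;
    missing or additional signature slots are filled deterministically
    from so-far-unused panel proteins with alternating signs.
    """
    available = list(protein_ids)
    used: set[str] = set()
    templates = list(SIGNATURE_TEMPLATES.values())
    raw: list[list[tuple[str, int]]] = []
    for c in range(len(config.cluster_sizes)):
        entries = []
        if c < len(templates):
            entries = [(p, s) for p, s in templates[c] if p in available]
        entries = entries[: config.signature_size]
        used.update(p for p, _ in entries)
        raw.append(entries)
    pool = [p for p in available if p not in used]
    for c, entries in enumerate(raw):
        while len(entries) < config.signature_size:
            if not pool:
                raise ValueError("not enough proteins to build disjoint signatures")
            p = pool.pop(0)
            entries.append((p, +1 if len(entries) % 2 == 0 else -1))
    return {
        cid: {p: s * config.effect_size for p, s in entries}
        for cid, entries in zip(config.cluster_ids, raw)
    }


def _plan(config: SimulationConfig):
    """Deterministic layout shared by primary and secondary screens."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0,)))
    panel = default_protein_panel(config.n_protein)
    signatures = cluster_signatures(config, panel)
    labels = np.concatenate(
        [np.full(s, cid) for s, cid in zip(config.cluster_sizes, config.cluster_ids)]
        + [np.full(config.n_null, config.null_cluster_id)]
    ).astype(int)
    order = rng.permutation(config.n_mirna)
    labels = labels[order]
    mirna_ids = [f"miR-{i + 1:04d}" for i in range(config.n_mirna)]
    return panel, signatures, mirna_ids, labels


def _mean_matrix(
    labels: np.ndarray,
    signatures: dict[int, dict[str, float]],
    protein_ids: Sequence[str],
) -> np.ndarray:
    col = {p: j for j, p in enumerate(protein_ids)}
    mean = np.zeros((len(labels), len(protein_ids)))
    for cid, sig in signatures.items():
        rows = np.flatnonzero(labels == cid)
        for p, eff in sig.items():
            if p in col:
                mean[rows, col[p]] = eff
    return mean


def simulate_primary_screen(
    config: SimulationConfig | None = None,
) -> tuple[ScreenMatrix, np.ndarray]:
    """Primary screen: signature + Gaussian noise rows, plus control rows.

    Returns the screen and the true cluster label per row.  Active-cluster
    rows carry their cluster's signed signature; null-cluster rows are
    noise only.  ``config.n_controls`` non-targeting control rows
    (ids ``NTC-...``, label 0) are appended for the normalization stage.
    """
    config = config or SimulationConfig()
    panel, signatures, mirna_ids, labels = _plan(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    mean = _mean_matrix(labels, signatures, panel)
    values = mean + rng.normal(0.0, config.noise_sd, size=mean.shape)
    if config.n_controls:
        ctrl = rng.normal(0.0, config.noise_sd, size=(config.n_controls, len(panel)))
        values = np.vstack([values, ctrl])
        mirna_ids = mirna_ids + [f"NTC-{i + 1:02d}" for i in range(config.n_controls)]
        labels = np.concatenate([labels, np.zeros(config.n_controls, dtype=int)])
    screen = ScreenMatrix(mirna_ids, panel, values, cell_line="A", screen_id="screen1")
    return screen, labels


def simulate_proliferation(
    screen: ScreenMatrix,
    activator_ids: Sequence[str] = DEFAULT_ACTIVATORS,
    repressor_ids: Sequence[str] = DEFAULT_REPRESSORS,
    beta: float = 0.12,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> ProliferationTable:
    """Relative cell-number change linearly coupled to protein responses.

    ``rel_change_i = beta * (mean over activators - mean over repressors
    of row i) + N(0, noise_sd)``.  Groups are left unset; binning is the
    job of :func:`mirscreen.proliferation.bin_proliferation`.
    """
    act = list(activator_ids)
    rep = list(repressor_ids)
    if set(act) & set(rep):
        raise ValueError(f"activators and repressors overlap: {sorted(set(act) & set(rep))}")
    missing = (set(act) | set(rep)) - set(screen.protein_ids)
    if missing:
        raise ValueError(f"proteins not in screen: {sorted(missing)}")
    df = screen.to_frame()
    act_mean = df[act].mean(axis=1).to_numpy() if act else np.zeros(len(df))
    rep_mean = df[rep].mean(axis=1).to_numpy() if rep else np.zeros(len(df))
    signal = act_mean - rep_mean
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(10,)))
    rel = beta * signal + rng.normal(0.0, noise_sd, size=len(signal))
    return ProliferationTable(list(screen.mirna_ids), rel)


# ---------------------------------------------------------------------------
# Planted Gaussian graphical models
# ---------------------------------------------------------------------------

@dataclass
class PlantedGGM:
    """Sparse positive-definite precision matrix with known support."""

    precision: np.ndarray
    support: frozenset[tuple[int, int]]
    cell_line: str = ""
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.precision = np.asarray(self.precision, dtype=float)
        p = self.precision.shape[0]
        if self.precision.shape != (p, p) or not np.allclose(
            self.precision, self.precision.T, atol=1e-10
        ):
            raise ValueError("precision must be square symmetric")
        if np.linalg.eigvalsh(self.precision).min() <= 0:
            raise ValueError("precision must be positive-definite")
        self.support = frozenset(
            (min(i, j), max(i, j)) for i, j in self.support
        )
        if any(i == j for i, j in self.support):
            raise ValueError("support must not contain self-edges")
        if not self.proteins:
            self.proteins = [f"V{i:02d}" for i in range(p)]

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def covariance(self) -> np.ndarray:
        return np.linalg.inv(self.precision)

    def support_ids(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            tuple(sorted((self.proteins[i], self.proteins[j])))
            for i, j in self.support
        )


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj); unit diagonal."""
    d = np.sqrt(np.diag(precision))
    rho = -precision / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def _build_precision(
    p: int,
    edges: Sequence[tuple[int, int]],
    signs: np.ndarray,
    target: float | np.ndarray,
    min_eig: float = 0.15,
) -> np.ndarray | None:
    """Precision realizing the requested partial correlations exactly.

    With a unit diagonal, setting ``Theta_ij = -sign * rho`` makes the
    partial correlation of edge (i, j) exactly ``sign * rho``.  Returns
    None when the resulting matrix's smallest eigenvalue falls below
    ``min_eig`` (the requested pattern is then too strong for the
    support; callers resample the random part of the support instead of
    distorting the magnitudes).
    """
    if not edges:
        return np.eye(p)
    target = np.broadcast_to(np.asarray(target, dtype=float), (len(edges),))
    theta = np.eye(p)
    for (i, j), sg, rho in zip(edges, signs, target):
        theta[i, j] = theta[j, i] = -sg * rho  # -Theta_ij carries the rho sign
    if np.linalg.eigvalsh(theta).min() < min_eig:
        return None
    return theta


def _degree_capped_pairs(
    p: int,
    n_edges: int,
    rng: np.random.Generator,
    max_degree: int,
    forced: Sequence[tuple[int, int]] = (),
) -> list[tuple[int, int]]:
    """Random distinct pairs with every node's degree capped.

    Bounded degree keeps the planted precision well conditioned (each
    node's partial-correlation budget stays well inside the
    positive-definite region), matching the sparse hub-free topology of
    signaling networks.
    """
    deg = np.zeros(p, dtype=int)
    edges = [(min(i, j), max(i, j)) for i, j in forced]
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
    pool = [(i, j) for i in range(p) for j in range(i + 1, p)
            if (i, j) not in set(edges)]
    order = rng.permutation(len(pool))
    for k in order:
        if len(edges) >= n_edges:
            break
        i, j = pool[k]
        if deg[i] < max_degree and deg[j] < max_degree:
            edges.append((i, j))
            deg[i] += 1
            deg[j] += 1
    if len(edges) < n_edges:
        raise ValueError(
            f"cannot place {n_edges} edges on {p} nodes with max degree {max_degree}"
        )
    return edges


def random_sparse_precision(
    p: int,
    n_edges: int,
    partial_corr_magnitude: float = 0.35,
    seed: int = 0,
    edges: Sequence[tuple[int, int]] | None = None,
    proteins: Sequence[str] | None = None,
    cell_line: str = "",
    max_degree: int = 3,
) -> PlantedGGM:
    """Random symmetric positive-definite precision with exact sparse support.

    Exactly ``n_edges`` off-diagonal pairs are nonzero (node degrees
    capped at ``max_degree`` for conditioning) and every planted edge has
    |partial correlation| exactly equal to the requested magnitude.  The
    random support is resampled until the precision is positive-definite
    with margin.
    """
    max_edges = p * (p - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"n_edges = {n_edges} exceeds p(p-1)/2 = {max_edges}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(20,)))
    if edges is not None:
        edges = [(min(i, j), max(i, j)) for i, j in edges]
        if len(set(edges)) != n_edges:
            raise ValueError("edges must contain n_edges distinct pairs")
        signs = rng.choice([-1.0, 1.0], size=len(edges))
        theta = _build_precision(p, edges, signs, partial_corr_magnitude)
        if theta is None:
            raise ValueError(
                "requested support/magnitude is not positive-definite with margin"
            )
        return PlantedGGM(theta, frozenset(edges), cell_line=cell_line,
                          proteins=list(proteins) if proteins else [])
    for _ in range(200):
        cand = _degree_capped_pairs(p, n_edges, rng, max_degree)
        signs = rng.choice([-1.0, 1.0], size=len(cand))
        theta = _build_precision(p, cand, signs, partial_corr_magnitude)
        if theta is not None:
            return PlantedGGM(theta, frozenset(cand), cell_line=cell_line,
                              proteins=list(proteins) if proteins else [])
    raise ValueError(
        f"no positive-definite support found for p={p}, n_edges={n_edges}, "
        f"|rho|={partial_corr_magnitude}; lower the magnitude or edge count"
    )


def planted_cell_line_ggms(
    p: int = 20,
    n_core: int = 8,
    n_mutant_shared: int = 9,
    n_lineage_shared: int = 1,
    n_unique: int = 2,
    partial_corr_magnitude: float = 0.40,
    core_magnitude: float = 0.42,
    seed: int = 0,
    proteins: Sequence[str] | None = None,
) -> tuple[dict[str, PlantedGGM], dict[str, frozenset[tuple[int, int]]]]:
    """Three cell-line precisions with a planted shared/specific edge design.

    Default topology: 8 core edges common to all lines, 9 edges shared by
    the two mutant lines (A, B) only, 1 edge shared by the two same-tissue
    lines (B, C) only, and ``n_unique`` private edges per line.  Shared
    edges keep the same sign in every line carrying them, and core edges
    are planted at a higher magnitude (``core_magnitude``) than the rest:
    links conserved across cellular backgrounds are the strongest ones.

    Returns the per-line models and the edge classes
    (``core`` / ``mutant_shared`` / ``lineage_shared`` / ``unique_A``...).
    """
    if proteins is None and p == 20:
        proteins = list(PHOSPHO_PANEL)
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(21,)))
    all_pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    name_to_idx = {name: i for i, name in enumerate(proteins)} if proteins else {}

    fixed_core: list[tuple[int, int]] = []
    if proteins is not None and all(a in name_to_idx and b in name_to_idx
                                    for a, b in CORE_EDGES[:n_core]):
        for a, b in CORE_EDGES[:n_core]:
            i, j = sorted((name_to_idx[a], name_to_idx[b]))
            fixed_core.append((i, j))

    for _ in range(500):
        core = list(fixed_core)
        taken = set(core)
        # node degrees capped per line for conditioning; an edge loads only
        # the lines that carry it
        deg = {line: np.zeros(p, dtype=int) for line in ("A", "B", "C")}
        for line in deg:
            for i, j in core:
                deg[line][i] += 1
                deg[line][j] += 1
        free = [e for e in all_pairs if e not in taken]
        rng.shuffle(free)

        def take(n, lines, cap=2):
            out = []
            k = 0
            while len(out) < n and k < len(free):
                i, j = free[k]
                if all(deg[l][i] < cap and deg[l][j] < cap for l in lines):
                    out.append(free.pop(k))
                    for l in lines:
                        deg[l][i] += 1
                        deg[l][j] += 1
                else:
                    k += 1
            if len(out) < n:
                raise ValueError(
                    "not enough degree-feasible protein pairs for the design"
                )
            taken.update(out)
            return out

        try:
            if len(core) < n_core:
                core += take(n_core - len(core), ("A", "B", "C"))
            mutant = take(n_mutant_shared, ("A", "B"))
            lineage = take(n_lineage_shared, ("B", "C"))
            uniq = {line: take(n_unique, (line,)) for line in ("A", "B", "C")}
        except ValueError:
            continue  # this shuffle cannot host the design; resample

        sign_of = {e: rng.choice([-1.0, 1.0]) for e in sorted(taken)}
        core_set = set(core)
        supports = {
            "A": core + mutant + uniq["A"],
            "B": core + mutant + lineage + uniq["B"],
            "C": core + lineage + uniq["C"],
        }
        ggms = {}
        for line, edges in supports.items():
            signs = np.array([sign_of[e] for e in edges])
            targets = np.array([core_magnitude if e in core_set
                                else partial_corr_magnitude for e in edges])
            theta = _build_precision(p, edges, signs, targets)
            if theta is None:
                break  # pattern too strong for this placement; resample
            ggms[line] = PlantedGGM(theta, frozenset(edges), cell_line=line,
                                    proteins=list(proteins) if proteins else [])
        if len(ggms) == 3:
            classes = {
                "core": frozenset(core),
                "mutant_shared": frozenset(mutant),
                "lineage_shared": frozenset(lineage),
                "unique_A": frozenset(uniq["A"]),
                "unique_B": frozenset(uniq["B"]),
                "unique_C": frozenset(uniq["C"]),
            }
            return ggms, classes
    raise ValueError(
        "no positive-definite placement found for the requested shared-edge design"
    )


def sample_ggm(ggm: PlantedGGM, n: int, seed: int = 0) -> np.ndarray:
    """Draw ``n`` i.i.d. rows from N(0, inverse precision)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(22,)))
    L = np.linalg.cholesky(ggm.covariance)
    return rng.standard_normal((n, ggm.p)) @ L.T


# ---------------------------------------------------------------------------
# Secondary screens
# ---------------------------------------------------------------------------

@dataclass
class SecondaryScreens:
    """Secondary screens plus the ground truth planted into them."""

    screens: list[ScreenMatrix]
    labels: np.ndarray                 # cluster id per subset miRNA
    shared_protein_ids: list[str]      # proteins common with the primary screen
    regulators: pd.DataFrame           # columns: mirna, protein, sign
    ggms: dict[str, PlantedGGM]


def simulate_secondary_screens(
    config: SimulationConfig,
    planted_ggms: dict[str, PlantedGGM] | None = None,
    n_mirna_subset: int = 154,
    shared_proteins: int = 103,
    flip_prob: float = 0.0,
    n_regulators: int = 6,
    regulator_targets: int = 3,
    regulator_effect: float = 3.5,
    seed: int | None = None,
) -> SecondaryScreens:
    """Re-screen a cluster-stratified miRNA subset in three cell lines.

    Each line's rows combine three planted components:

    * cluster signature means on shared non-phospho proteins (each entry's
      sign flipped independently with probability ``flip_prob`` to emulate
      imperfect replication);
    * a phosphoprotein block drawn from N(0, inverse planted precision)
      for that line, on top of sparse per-miRNA regulator shifts
      (``n_regulators`` miRNAs x ``regulator_targets`` phospho targets at
      +-``regulator_effect``, consistent across the three lines);
    * i.i.d. N(0, noise_sd) residuals on all non-phospho proteins.

    Cluster-level signature means are deliberately kept off the phospho
    block so that the block's covariance follows the planted graphical
    model the inference stage assumes.
    """
    if not 0.0 <= flip_prob <= 1.0:
        raise ValueError(f"flip_prob must be in [0, 1], got {flip_prob}")
    if seed is None:
        seed = config.seed
    panel, signatures, mirna_ids, labels = _plan(config)
    if planted_ggms is None:
        planted_ggms, _ = planted_cell_line_ggms(seed=seed)
    if shared_proteins > config.n_protein:
        raise ValueError("shared_proteins exceeds the primary panel size")

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    shared = panel[:shared_proteins]
    n_new = config.n_protein - shared_proteins
    new = [f"S2AB{i:03d}" for i in range(1, n_new + 1)]
    protein_ids = shared + new

    any_ggm = next(iter(planted_ggms.values()))
    phospho = any_ggm.proteins
    missing = set(phospho) - set(shared)
    if missing:
        raise ValueError(f"GGM proteins not in the shared panel: {sorted(missing)}")
    phospho_cols = [protein_ids.index(p) for p in phospho]
    other_cols = [j for j in range(len(protein_ids)) if j not in set(phospho_cols)]

    # stratified subset: proportional per cluster, deterministic
    subset_idx: list[int] = []
    all_cids = list(config.cluster_ids) + [config.null_cluster_id]
    quota = {}
    for cid in all_cids:
        members = np.flatnonzero(labels == cid)
        quota[cid] = int(round(n_mirna_subset * len(members) / config.n_mirna))
    # fix rounding so quotas sum exactly
    diff = n_mirna_subset - sum(quota.values())
    quota[config.null_cluster_id] += diff
    for cid in all_cids:
        members = np.flatnonzero(labels == cid)
        pick = rng.choice(members, size=quota[cid], replace=False)
        subset_idx.extend(sorted(pick))
    subset_idx = sorted(subset_idx)
    sub_ids = [mirna_ids[i] for i in subset_idx]
    sub_labels = labels[subset_idx]

    # planted regulators: null-cluster miRNAs with strong phospho shifts
    null_rows = np.flatnonzero(sub_labels == config.null_cluster_id)
    reg_rows = rng.choice(null_rows, size=min(n_regulators, len(null_rows)),
                          replace=False)
    reg_records = []
    reg_shift = np.zeros((n_mirna_subset, len(phospho)))
    for r in sorted(reg_rows):
        targets = rng.choice(len(phospho), size=regulator_targets, replace=False)
        sg = int(rng.choice([-1, 1]))  # one direction per regulator
        for t in sorted(targets):
            reg_shift[r, t] = sg * regulator_effect
            reg_records.append({"mirna": sub_ids[r], "protein": phospho[t],
                                "sign": sg})
    regulators = pd.DataFrame(reg_records, columns=["mirna", "protein", "sign"])

    # cluster signature means on shared non-phospho proteins
    base_mean = np.zeros((n_mirna_subset, len(protein_ids)))
    col = {pid: j for j, pid in enumerate(protein_ids)}
    phospho_set = set(phospho)
    for cid, sig in signatures.items():
        rows = np.flatnonzero(sub_labels == cid)
        for pid, eff in sig.items():
            if pid in col and pid not in phospho_set:
                base_mean[rows, col[pid]] = eff

    screens = []
    for line_no, line in enumerate(sorted(planted_ggms)):
        ggm = planted_ggms[line]
        line_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(3, line_no))
        )
        mean = base_mean.copy()
        if flip_prob > 0:
            nz = mean != 0
            flips = line_rng.random(mean.shape) < flip_prob
            mean = np.where(nz & flips, -mean, mean)
        values = np.zeros_like(mean)
        values[:, other_cols] = (
            mean[:, other_cols]
            + line_rng.normal(0.0, config.noise_sd, size=(n_mirna_subset, len(other_cols)))
        )
        cov = ggm.covariance
        L = np.linalg.cholesky(cov)
        block = line_rng.standard_normal((n_mirna_subset, ggm.p)) @ L.T
        # regulator effects are planted in units of each protein's marginal
        # SD so a call is a fixed number of robust-z units in every line
        values[:, phospho_cols] = block + reg_shift * np.sqrt(np.diag(cov))
        screens.append(
            ScreenMatrix(sub_ids, protein_ids, values, cell_line=line,
                         screen_id="screen2")
        )
    return SecondaryScreens(screens, sub_labels, shared, regulators, dict(planted_ggms))
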