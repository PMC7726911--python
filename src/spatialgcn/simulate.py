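"""Synthetic spatial expression datasets with known gene-gene couplings.

The generator emulates the structure of multiplexed in-situ transcriptomics
data (seqFISH+/MERFISH-like): a few hundred to a couple of thousand cells
scattered uniformly over one or more square fields of view, sparse
overdispersed transcript counts for hundreds of genes, and a designated
subset of ordered gene pairs whose expression is coupled.

Every gene that is not a coupled receptor gets a spatially clustered mean
field — a sum of Gaussian bumps at random centers, rescaled to a unit mean
so the average expression stays at ``base_rate`` — and counts are drawn
from a negative binomial (gamma-Poisson) around that field.  For a
positive pair (g_L, g_R):

* exocrine mode: the receptor's mean in cell i is
  ``base_rate + coupling_strength * sum_{j in N(i)} count_L[j]`` where
  N(i) are i's neighbors within ``radius`` — signal travels between
  neighboring cells only;
* autocrine mode: ``base_rate + coupling_strength * count_L[i]`` — the
  coupling is within the same cell;
* mixed mode alternates pairs between the two.

Unpaired genes are spatially clustered but independent of every ligand, so
sampled negatives are not trivially flat.  All randomness flows from one
seed and outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, normalize_counts, read_counts, write_counts
from .graph import AdjacencyMatrix, CellCoordinates, compute_adjacency, read_coordinates

__all__ = ["SimConfig", "SimTruth", "SimulatedDataset", "simulate", "write_fixture", "read_fixture"]


@dataclass
class SimConfig:
    """Generator settings.

    Defaults emulate a mid-sized two-FOV imaging dataset: 500 cells in two
    1000 x 1000 fields, 500 genes at a mean of 5 transcripts per cell, an
    interaction radius of 100 image units (average degree around 8), and
    40 coupled ligand-receptor pairs with strong exocrine coupling.

    The default noise regime is deliberately neighbor-mediated: expression
    hotspots are compact (``bump_sigma_frac`` below the interaction radius
    relative to the arena) and counts strongly overdispersed
    (``noise_dispersion=1``), so a receptor's best predictor is the summed
    ligand count of its neighbors rather than its own cell's noisy ligand
    count — the regime in which spatial context genuinely matters.
    """

    n_cells: int = 500
    n_fov: int = 2
    arena: float = 1000.0
    radius: float = 100.0
    n_genes: int = 500
    n_pos_pairs: int = 40
    coupling_mode: str = "exocrine"
    coupling_strength: float = 1.0
    base_rate: float = 5.0
    noise_dispersion: float = 1.0
    n_bumps: int = 3
    bump_sigma_frac: float = 0.06
    shared_field_strength: float = 0.0
    shared_field_sigma_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos_pairs * 2 > self.n_genes:
            raise ValueError("need n_genes >= 2 * n_pos_pairs")
        if not 0 < self.radius < self.arena:
            raise ValueError("radius must lie in (0, arena)")
        if self.coupling_mode not in {"exocrine", "autocrine", "mixed"}:
            raise ValueError(f"unknown coupling_mode {self.coupling_mode!r}")
        if self.base_rate <= 0 or self.noise_dispersion <= 0:
            raise ValueError("base_rate and noise_dispersion must be positive")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be nonnegative")
        if not 0 <= self.shared_field_strength <= 1:
            raise ValueError("shared_field_strength must be in [0, 1]")
        if self.n_cells < self.n_fov:
            raise ValueError("need at least one cell per field of view")


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset."""

    positive_pairs: list[tuple[str, str]]
    negative_pool: list[str]
    true_adjacency: AdjacencyMatrix
    pair_modes: dict[tuple[str, str], str] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """Coordinates, integer counts, and the generating truth."""

    coords: CellCoordinates
    counts: np.ndarray
    gene_ids: np.ndarray
    truth: SimTruth
    config: SimConfig

    @property
    def cell_ids(self) -> np.ndarray:
        return self.coords.cell_id

    def expression(self) -> ExpressionMatrix:
        return normalize_counts(self.counts, gene_ids=self.gene_ids,
                                cell_ids=self.cell_ids)


def _bump_field(
    rng: np.random.Generator,
    coords: CellCoordinates,
    cfg: SimConfig,
    n_bumps: int | None = None,
    sigma_frac: float | None = None,
) -> np.ndarray:
    """Smooth Gaussian-bump intensity per cell, rescaled to mean 1."""
    n_bumps = cfg.n_bumps if n_bumps is None else n_bumps
    sigma_frac = cfg.bump_sigma_frac if sigma_frac is None else sigma_frac
    sigma = sigma_frac * cfg.arena
    if n_bumps <= 0:
        return np.ones(len(coords))
    raw = np.zeros(len(coords))
    for fov in pd.unique(coords.fov):
        idx = np.flatnonzero(coords.fov == fov)
        centers = rng.uniform(0, cfg.arena, size=(n_bumps, 2))
        pts = np.column_stack([coords.x[idx], coords.y[idx]])
        d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        raw[idx] = np.exp(-d2 / (2 * sigma**2)).sum(axis=1)
    mean = raw.mean()
    if mean <= 0:
        return np.ones(len(coords))
    return raw / mean


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixing; var = mu + mu^2/theta."""
    mean = np.maximum(mean, 1e-9)
    lam = mean * rng.gamma(shape=dispersion, scale=1.0 / dispersion, size=mean.shape)
    return rng.poisson(lam)


def simulate(cfg: SimConfig) -> SimulatedDataset:
    """Draw one dataset: coordinates, counts, and ground truth."""
    rng = np.random.default_rng(cfg.seed)

    # --- cell layout ---------------------------------------------------
    fov_sizes = [len(chunk) for chunk in np.array_split(np.arange(cfg.n_cells), cfg.n_fov)]
    fov_labels = np.concatenate(
        [np.full(sz, f"fov{f}", dtype=object) for f, sz in enumerate(fov_sizes)]
    )
    coords = CellCoordinates(
        cell_id=np.array([f"cell{i:04d}" for i in range(cfg.n_cells)], dtype=object),
        x=rng.uniform(0, cfg.arena, cfg.n_cells),
        y=rng.uniform(0, cfg.arena, cfg.n_cells),
        fov=fov_labels,
    )
    adj = compute_adjacency(coords, cfg.radius)

    # --- gene roles ----------------------------------------------------
    P = cfg.n_pos_pairs
    ligands = [f"LG{i:03d}" for i in range(P)]
    receptors = [f"RC{i:03d}" for i in range(P)]
    background = [f"BG{i:03d}" for i in range(cfg.n_genes - 2 * P)]
    gene_ids = np.array(ligands + receptors + background, dtype=object)

    counts = np.zeros((cfg.n_cells, cfg.n_genes), dtype=np.int64)
    pair_modes: dict[tuple[str, str], str] = {}

    # optional zonation: one broad regional field modulating every gene,
    # emulating cell-type/region programs that induce long-range
    # co-expression unrelated to short-range signaling
    w = cfg.shared_field_strength
    if w > 0:
        zonation = (1 - w) + w * _bump_field(
            rng, coords, cfg, n_bumps=2, sigma_frac=cfg.shared_field_sigma_frac
        )
    else:
        zonation = np.ones(cfg.n_cells)

    # --- ligands: clustered NB fields; receptors: coupled to them ------
    for i in range(P):
        field_l = _bump_field(rng, coords, cfg)
        count_l = _nb_counts(
            rng, cfg.base_rate * field_l * zonation, cfg.noise_dispersion
        )
        counts[:, i] = count_l
        if cfg.coupling_mode == "mixed":
            mode = "exocrine" if i % 2 == 0 else "autocrine"
        else:
            mode = cfg.coupling_mode
        pair_modes[(ligands[i], receptors[i])] = mode
        if mode == "exocrine":
            drive = np.asarray(adj.A @ count_l).ravel()
        else:
            drive = count_l.astype(float)
        mean_r = (cfg.base_rate + cfg.coupling_strength * drive) * zonation
        counts[:, P + i] = _nb_counts(rng, mean_r, cfg.noise_dispersion)

    # --- background: clustered but independent -------------------------
    for j in range(len(background)):
        field_b = _bump_field(rng, coords, cfg)
        counts[:, 2 * P + j] = _nb_counts(
            rng, cfg.base_rate * field_b * zonation, cfg.noise_dispersion
        )

    truth = SimTruth(
        positive_pairs=list(zip(ligands, receptors)),
        negative_pool=background,
        true_adjacency=adj,
        pair_modes=pair_modes,
    )
    return SimulatedDataset(
        coords=coords, counts=counts, gene_ids=gene_ids, truth=truth, config=cfg
    )


def write_fixture(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write the dataset in the same plain-text formats the readers consume.

    coordinates TSV + counts MTX (+ gene/cell sidecars) + truth TSV +
    config JSON; the files round-trip losslessly through ``read_fixture``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    coords_path = directory / "coordinates.tsv"
    dataset.coords.to_frame().to_csv(coords_path, sep="\t", index=False)
    paths["coordinates"] = coords_path
    expr = normalize_counts(dataset.counts, dataset.gene_ids, dataset.cell_ids)
    paths.update(write_counts(expr, directory))
    truth_path = directory / "truth_pairs.tsv"
    pd.DataFrame(
        [
            (l, r, dataset.truth.pair_modes.get((l, r), dataset.config.coupling_mode))
            for l, r in dataset.truth.positive_pairs
        ],
        columns=["ligand", "receptor", "mode"],
    ).to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    config_path = directory / "config.json"
    config_path.write_text(json.dumps(asdict(dataset.config), indent=2, sort_keys=True))
    paths["config"] = config_path
    return paths


def read_fixture(directory: str | Path) -> SimulatedDataset:
    """Re-load a written fixture through the standard readers."""
    directory = Path(directory)
    cfg = SimConfig(**json.loads((directory / "config.json").read_text()))
    coords = read_coordinates(directory / "coordinates.tsv")
    expr = read_counts(directory / "counts.mtx")
    truth_df = pd.read_csv(directory / "truth_pairs.tsv", sep="\t")
    pairs = [(str(l), str(r)) for l, r in zip(truth_df["ligand"], truth_df["receptor"])]
    modes = {
        (str(l), str(r)): str(m)
        for l, r, m in zip(truth_df["ligand"], truth_df["receptor"], truth_df["mode"])
    }
    paired = {g for p in pairs for g in p}
    pool = [g for g in expr.gene_ids if g not in paired]
    adj = compute_adjacency(coords, cfg.radius)
    truth = SimTruth(
        positive_pairs=pairs, negative_pool=pool, true_adjacency=adj, pair_modes=modes
    )
    return SimulatedDataset(
        coords=coords,
        counts=expr.counts.astype(np.int64),
        gene_ids=expr.gene_ids,
        truth=truth,
        config=cfg,
    )
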