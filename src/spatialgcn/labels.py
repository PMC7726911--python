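"""Labeled gene pairs and leakage-free cross-validation folds.

The classifier is trained on ordered gene pairs: known ligand-receptor
interactions are positives, and each positive (L_a, R_b) is matched with a
negative (L_a, R_x) whose receptor R_x is drawn from the same side's
receptor pool and is not a known partner of L_a, giving exact 1:1 balance.

Cross-validation is gene-exclusive: in every fold, 90% of ligands and 90%
of receptors go to the training side and the rest to the test side; any
pair mixing a train gene with a test gene is removed, so no gene seen in
training ever appears in a test pair.  A gene that acts as both ligand and
receptor is assigned to one side as a single entity.  20% of the training
pairs (round half up) are held out as a validation set used for early
stopping and distance-threshold selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionList",
    "PairSample",
    "FoldPlan",
    "load_interactions",
    "make_folds",
    "sample_negatives",
    "direction_pairs",
    "function_pairs",
    "permute_interactions",
    "read_gene_set",
]


@dataclass(frozen=True)
class PairSample:
    """One ordered gene pair with its binary label and task tag."""

    gene_a: str
    gene_b: str
    label: int
    task: str = "interaction"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


@dataclass
class InteractionList:
    """A directed ligand -> receptor pair list."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for pair in self.pairs:
            pair = (str(pair[0]), str(pair[1]))
            if pair not in seen:
                seen.add(pair)
                deduped.append(pair)
        self.pairs = deduped

    @property
    def ligands(self) -> list[str]:
        return sorted({l for l, _ in self.pairs})

    @property
    def receptors(self) -> list[str]:
        return sorted({r for _, r in self.pairs})

    @property
    def genes(self) -> list[str]:
        return sorted({g for pair in self.pairs for g in pair})

    def partners(self, ligand: str) -> set[str]:
        return {r for l, r in self.pairs if l == ligand}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in set(self.pairs)


@dataclass
class FoldPlan:
    """Train/validation/test pair samples for one gene-exclusive fold."""

    fold_id: int
    train_ligands: set[str]
    test_ligands: set[str]
    train_receptors: set[str]
    test_receptors: set[str]
    train_samples: list[PairSample]
    test_samples: list[PairSample]
    validation_samples: list[PairSample] = field(default_factory=list)

    @property
    def train_genes(self) -> set[str]:
        return self.train_ligands | self.train_receptors

    @property
    def test_genes(self) -> set[str]:
        return self.test_ligands | self.test_receptors

    def audit(self) -> None:
        """Raise if any sample leaks a gene across the train/test split."""
        if self.train_genes & self.test_genes:
            raise AssertionError("train and test gene sets overlap")
        for s in self.train_samples + self.validation_samples:
            if {s.gene_a, s.gene_b} & self.test_genes:
                raise AssertionError(f"train-side sample {s} uses a test gene")
        for s in self.test_samples:
            if {s.gene_a, s.gene_b} & self.train_genes:
                raise AssertionError(f"test sample {s} uses a train gene")


def load_interactions(
    path: str | Path, expr: ExpressionMatrix | None = None
) -> InteractionList:
    """Read a ligand/receptor TSV and keep pairs whose genes are measured.

    Unmatched genes are reported with a warning, never silently dropped.
    Gene matching against the expression matrix is case-insensitive with an
    exact-match preference.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"ligand", "receptor"} - set(df.columns)
    if missing:
        raise ValueError(f"interaction list missing columns: {sorted(missing)}")
    pairs = [(str(l), str(r)) for l, r in zip(df["ligand"], df["receptor"])]
    if expr is not None:
        kept, dropped_genes = [], set()
        for l, r in pairs:
            ok = True
            for g in (l, r):
                if not expr.has_gene(g):
                    dropped_genes.add(g)
                    ok = False
            if ok:
                kept.append((l, r))
        if dropped_genes:
            logger.warning(
                "%d interaction gene(s) absent from expression matrix: %s",
                len(dropped_genes),
                ", ".join(sorted(dropped_genes)[:10]),
            )
        if not kept:
            raise ValueError("no interaction pair overlaps the expression genes")
        pairs = kept
    return InteractionList(pairs=pairs)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sample_negatives(
    positives: Sequence[PairSample],
    interactions: InteractionList,
    receptor_pool: Iterable[str],
    seed: int | np.random.Generator,
) -> list[PairSample]:
    """One matched negative (L_a, R_x) per positive (L_a, R_b).

    R_x is drawn uniformly from ``receptor_pool`` minus L_a's known
    partners (and L_a itself), so negatives are never known interactions
    and the resulting sample set is exactly balanced.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pool = sorted(set(receptor_pool))
    negatives = []
    for pos in positives:
        candidates = [
            r for r in pool if r not in interactions.partners(pos.gene_a) and r != pos.gene_a
        ]
        if not candidates:
            raise ValueError(
                f"no negative receptor available for ligand {pos.gene_a!r}"
            )
        choice = candidates[rng.integers(len(candidates))]
        negatives.append(PairSample(pos.gene_a, choice, 0, task=pos.task))
    return negatives


def make_folds(
    interactions: InteractionList,
    k: int = 10,
    seed: int = 0,
    task: str = "interaction",
) -> list[FoldPlan]:
    """Gene-exclusive k-fold plans with balanced negatives and validation.

    Ligands (including dual-role genes) and pure receptors are each
    shuffled and partitioned into k test chunks; fold i tests on chunk i
    and trains on the rest, i.e. (k-1)/k of each role — 90% for the default
    k=10.  Pairs straddling the split are removed.  Negatives are sampled
    after the removal so balance is exact, and 20% of the training pairs
    (round half up) are then diverted to the validation set.
    """
    if len(interactions) == 0:
        raise ValueError("empty interaction list")
    rng = np.random.default_rng(seed)
    ligands = np.array(interactions.ligands, dtype=object)
    pure_receptors = np.array(
        sorted(set(interactions.receptors) - set(interactions.ligands)), dtype=object
    )
    rng.shuffle(ligands)
    rng.shuffle(pure_receptors)
    lig_chunks = np.array_split(ligands, k)
    rec_chunks = np.array_split(pure_receptors, k)

    folds = []
    for i in range(k):
        test_genes = set(lig_chunks[i]) | set(rec_chunks[i])
        train_genes = set(interactions.genes) - test_genes
        train_lig = {l for l in interactions.ligands if l in train_genes}
        test_lig = {l for l in interactions.ligands if l in test_genes}
        train_rec = {r for r in interactions.receptors if r in train_genes}
        test_rec = {r for r in interactions.receptors if r in test_genes}

        pos_train = [
            PairSample(l, r, 1, task=task)
            for l, r in interactions.pairs
            if l in train_genes and r in train_genes
        ]
        pos_test = [
            PairSample(l, r, 1, task=task)
            for l, r in interactions.pairs
            if l in test_genes and r in test_genes
        ]
        if not pos_test:
            logger.warning("fold %d has no test positives; it will be skipped", i)
        if not pos_train:
            logger.warning("fold %d has no train positives; it will be skipped", i)
            folds.append(
                FoldPlan(i, train_lig, test_lig, train_rec, test_rec, [], [])
            )
            continue

        neg_train = sample_negatives(pos_train, interactions, train_rec, rng)
        neg_test = (
            sample_negatives(pos_test, interactions, test_rec, rng) if pos_test else []
        )
        train_samples = pos_train + neg_train
        test_samples = pos_test + neg_test

        v_total = _round_half_up(0.2 * len(train_samples))
        v_pos = min(v_total // 2, len(pos_train))
        v_neg = min(v_total - v_pos, len(neg_train))
        pos_idx = rng.permutation(len(pos_train))
        neg_idx = rng.permutation(len(neg_train))
        val = [pos_train[j] for j in pos_idx[:v_pos]] + [
            neg_train[j] for j in neg_idx[:v_neg]
        ]
        train = [pos_train[j] for j in pos_idx[v_pos:]] + [
            neg_train[j] for j in neg_idx[v_neg:]
        ]

        fold = FoldPlan(
            fold_id=i,
            train_ligands=train_lig,
            test_ligands=test_lig,
            train_receptors=train_rec,
            test_receptors=test_rec,
            train_samples=train,
            test_samples=test_samples,
            validation_samples=val,
        )
        fold.audit()
        folds.append(fold)
    return folds


def direction_pairs(
    interactions: InteractionList | Iterable[tuple[str, str]],
) -> list[PairSample]:
    """Causal-direction samples: (L, R) labeled 1, the flipped (R, L) 0."""
    pairs = (
        interactions.pairs
        if isinstance(interactions, InteractionList)
        else [tuple(p) for p in interactions]
    )
    if not pairs:
        raise ValueError("no interaction pairs to orient")
    samples = []
    for l, r in pairs:
        samples.append(PairSample(l, r, 1, task="direction"))
        samples.append(PairSample(r, l, 0, task="direction"))
    return samples


def function_pairs(
    function_genes: Iterable[str],
    background: Iterable[str],
    seed: int = 0,
) -> list[PairSample]:
    """Function-assignment samples.

    Positives are all unordered pairs of genes within the function set;
    negatives pair a random function gene with a random background gene,
    matched 1:1.
    """
    fn = sorted(set(map(str, function_genes)))
    bg = sorted(set(map(str, background)) - set(fn))
    if len(fn) < 2:
        raise ValueError("need at least two function genes")
    if not bg:
        raise ValueError("background gene set is empty")
    rng = np.random.default_rng(seed)
    positives = [
        PairSample(a, b, 1, task="function") for a, b in combinations(fn, 2)
    ]
    negatives = [
        PairSample(
            fn[rng.integers(len(fn))], bg[rng.integers(len(bg))], 0, task="function"
        )
        for _ in positives
    ]
    return positives + negatives


def permute_interactions(interactions: InteractionList, seed: int) -> InteractionList:
    """Label permutation control: shuffle the receptor column.

    Receptors are randomly reassigned to ligands, preserving each ligand's
    pair count.  The overlap with the true list is logged.
    """
    if len(interactions) == 0:
        raise ValueError("empty interaction list")
    rng = np.random.default_rng(seed)
    ligs = [l for l, _ in interactions.pairs]
    recs = [r for _, r in interactions.pairs]
    permuted: list[tuple[str, str]] | None = None
    for _ in range(100):
        rec_perm = list(np.array(recs, dtype=object)[rng.permutation(len(recs))])
        candidate = list(zip(ligs, rec_perm))
        if len(set(candidate)) == len(candidate):
            permuted = candidate
            break
    if permuted is None:  # tiny lists may not admit a duplicate-free shuffle
        permuted = list(dict.fromkeys(candidate))
    overlap = len(set(permuted) & set(interactions.pairs))
    logger.info(
        "permuted interaction list overlaps truth in %d/%d pairs",
        overlap,
        len(interactions),
    )
    return InteractionList(pairs=permuted)


def read_gene_set(path: str | Path) -> list[str]:
    """Read a one-gene-per-line (.grp style) gene set; '#' lines ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes
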