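"""Label assembly and training-matrix construction for pHLA classification.

Positive labels are mass-spectrometry-eluted peptides (stable binders by
construction: the complex survived transport to the cell surface).
Negative labels come from binding-affinity assays, kept only above a
conservative 20,000 nM threshold so that low-affinity truly implies
unstable binding.

Two matrix modes mirror the two training datasets:

- ``single``: one row per pHLA, its best-scoring conformation;
- ``ensemble``: one row per modeled conformation, every row carrying the
  pHLA's label (prediction later averages per-conformation probabilities).

Sample weights equalize the weighted class masses (0.5/0.5), compensating
for the roughly 70:30 binder/non-binder imbalance of the source data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .featurize import FEATURE_NAMES, ContactFeaturizer, N_FEATURES
from .structure import STANDARD_AAS, StructureRecord, parse_structure

logger = logging.getLogger(__name__)

DEFAULT_AFFINITY_THRESHOLD_NM = 20_000.0

_ALLELE_RE = re.compile(r"^HLA-[A-Z]+\*?\d+(:\d+)*$")


def phla_id_of(peptide: str, allele: str) -> str:
    """Canonical pHLA identifier, filesystem-safe."""
    return f"{peptide}_{allele.replace('*', '').replace(':', '-')}"


def _validate_peptides(df: pd.DataFrame, table: str) -> None:
    bad = df.loc[~df["peptide"].map(lambda p: set(p) <= set(STANDARD_AAS)), "peptide"]
    if len(bad):
        raise ValueError(
            f"{table} table contains peptides outside the 20-letter alphabet: "
            f"{sorted(bad.unique())[:5]}"
        )
    bad_alleles = df.loc[~df["allele"].map(lambda a: bool(_ALLELE_RE.match(str(a)))), "allele"]
    if len(bad_alleles):
        raise ValueError(
            f"{table} table contains malformed allele names: "
            f"{sorted(bad_alleles.unique())[:5]} (expected e.g. HLA-A*01:01)"
        )


def build_labels(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    affinity_threshold_nM: float = DEFAULT_AFFINITY_THRESHOLD_NM,
    peptide_length: int | None = 9,
) -> pd.DataFrame:
    """Assemble labeled pHLA examples from positive and negative tables.

    Parameters
    ----------
    positives
        Eluted stable binders; columns ``peptide``, ``allele``.
    negatives
        Affinity-assayed pairs; columns ``peptide``, ``allele``,
        ``affinity_nM``.  Rows are kept only when the measured affinity
        exceeds ``affinity_threshold_nM`` (weak binding taken as evidence of
        unstable binding; sub-threshold rows are ambiguous and dropped).
    peptide_length
        Keep only peptides of this length (default 9; ``None`` disables the
        filter — the representation itself is length-agnostic).

    Returns
    -------
    DataFrame with columns ``phla_id, peptide, allele, label, source,
    affinity_nM``; label 1 = stable, 0 = unstable.  Duplicate
    (peptide, allele) pairs are deduplicated; pairs appearing in both tables
    are conflicting and dropped with a warning.  ``df.attrs`` records the
    filter counts (``n_affinity_excluded``, ``n_length_excluded``,
    ``n_conflicts``).
    """
    pos = positives.copy()
    neg = negatives.copy()
    for df, name, need in ((pos, "positives", {"peptide", "allele"}),
                           (neg, "negatives", {"peptide", "allele", "affinity_nM"})):
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks column(s) {sorted(missing)}")
        df["peptide"] = df["peptide"].astype(str) if len(df) else df["peptide"].astype(object)
    _validate_peptides(pos, "positives")
    _validate_peptides(neg, "negatives")
    if (neg["affinity_nM"] <= 0).any():
        raise ValueError("negatives table contains non-positive affinities")

    n_len = 0
    if peptide_length is not None:
        for name, df in (("positives", pos), ("negatives", neg)):
            keep = df["peptide"].str.len() == peptide_length
            n_len += int((~keep).sum())
        pos = pos[pos["peptide"].str.len() == peptide_length]
        neg = neg[neg["peptide"].str.len() == peptide_length]
        if n_len:
            logger.info("excluded %d rows with peptide length != %d", n_len, peptide_length)

    below = neg["affinity_nM"] <= affinity_threshold_nM
    n_excluded = int(below.sum())
    if n_excluded:
        logger.info(
            "excluded %d negative rows with affinity <= %.0f nM",
            n_excluded, affinity_threshold_nM,
        )
    neg = neg[~below]

    pos = pos.drop_duplicates(subset=["peptide", "allele"])
    neg = neg.drop_duplicates(subset=["peptide", "allele"])

    key_pos = set(map(tuple, pos[["peptide", "allele"]].itertuples(index=False)))
    key_neg = set(map(tuple, neg[["peptide", "allele"]].itertuples(index=False)))
    conflicts = key_pos & key_neg
    if conflicts:
        logger.warning(
            "dropping %d (peptide, allele) pairs labeled in both tables", len(conflicts)
        )
        mask = lambda df: ~df.apply(
            lambda r: (r["peptide"], r["allele"]) in conflicts, axis=1
        )
        pos = pos[mask(pos)]
        neg = neg[mask(neg)]

    out = pd.concat(
        [
            pd.DataFrame(
                {
                    "peptide": pos["peptide"],
                    "allele": pos["allele"],
                    "label": 1,
                    "source": "elution",
                    "affinity_nM": np.nan,
                }
            ),
            pd.DataFrame(
                {
                    "peptide": neg["peptide"],
                    "allele": neg["allele"],
                    "label": 0,
                    "source": "affinity_assay",
                    "affinity_nM": neg["affinity_nM"].astype(float),
                }
            ),
        ],
        ignore_index=True,
    )
    out.insert(0, "phla_id", [phla_id_of(p, a) for p, a in zip(out["peptide"], out["allele"])])
    out = out.sort_values("phla_id", kind="stable").reset_index(drop=True)
    out.attrs["n_affinity_excluded"] = n_excluded
    out.attrs["n_length_excluded"] = n_len
    out.attrs["n_conflicts"] = len(conflicts)
    logger.info(
        "assembled %d labeled pHLAs (%d stable, %d unstable)",
        len(out), int((out["label"] == 1).sum()), int((out["label"] == 0).sum()),
    )
    return out


class ConformationStore:
    """Interface to the conformations of each pHLA.

    Subclasses yield ``(conformation_id, StructureRecord)`` pairs per pHLA,
    in a deterministic (sorted) order, and optionally know a per-conformation
    score (lower is better, as for docking energies) used to pick the best
    conformation in ``single`` mode.
    """

    def phla_ids(self) -> list[str]:
        raise NotImplementedError

    def conformations(self, phla_id: str) -> list[tuple[str, StructureRecord]]:
        raise NotImplementedError

    def score(self, phla_id: str, conformation_id: str) -> float | None:
        return None

    def best_conformation(self, phla_id: str) -> tuple[str, StructureRecord]:
        confs = self.conformations(phla_id)
        if not confs:
            raise KeyError(f"no conformations for {phla_id}")
        scored = [(cid, self.score(phla_id, cid)) for cid, _ in confs]
        if all(s is None for _, s in scored):
            logger.warning(
                "%s: no conformation scores available; taking the first "
                "conformation lexicographically", phla_id,
            )
            return confs[0]
        best = min(
            (s, cid) for cid, s in scored if s is not None
        )[1]
        return next((cid, rec) for cid, rec in confs if cid == best)


class DirectoryStore(ConformationStore):
    """Directory layout: one subdirectory per pHLA, one PDB per conformation.

    An optional ``scores.csv`` at the root (columns ``phla_id,
    conformation_id, score``) supplies per-conformation scores; lower is
    better.
    """

    def __init__(self, root: str | Path, chain_map: Mapping[str, str] | None = None):
        self.root = Path(root)
        self.chain_map = chain_map
        self._scores: dict[tuple[str, str], float] = {}
        scores_path = self.root / "scores.csv"
        if scores_path.exists():
            df = pd.read_csv(scores_path)
            self._scores = {
                (r.phla_id, r.conformation_id): float(r.score)
                for r in df.itertuples()
            }

    def phla_ids(self) -> list[str]:
        return sorted(p.name for p in self.root.iterdir() if p.is_dir())

    def conformations(self, phla_id: str) -> list[tuple[str, StructureRecord]]:
        out = []
        for pdb in sorted((self.root / phla_id).glob("*.pdb")):
            rec = parse_structure(
                pdb, chain_map=self.chain_map,
                phla_id=phla_id, conformation_id=pdb.stem,
            )
            out.append((pdb.stem, rec))
        return out

    def score(self, phla_id: str, conformation_id: str) -> float | None:
        return self._scores.get((phla_id, conformation_id))


class MemoryStore(ConformationStore):
    """In-memory store: mapping phla_id -> list of StructureRecord."""

    def __init__(
        self,
        records: Mapping[str, Sequence[StructureRecord]],
        scores: Mapping[tuple[str, str], float] | None = None,
    ):
        self._records = {k: list(v) for k, v in records.items()}
        self._score_table = dict(scores or {})

    def phla_ids(self) -> list[str]:
        return sorted(self._records)

    def conformations(self, phla_id: str) -> list[tuple[str, StructureRecord]]:
        return sorted(
            ((rec.conformation_id, rec) for rec in self._records[phla_id]),
            key=lambda t: t[0],
        )

    def score(self, phla_id: str, conformation_id: str) -> float | None:
        return self._score_table.get((phla_id, conformation_id))


@dataclass
class TrainingMatrix:
    """Feature matrix with labels, pHLA group ids, alleles and weights.

    ``groups`` carries the pHLA identifier of each row so that grouped fold
    construction never splits the conformations of one pHLA across
    train/test.  ``sample_weight`` equalizes the weighted class masses: the
    weighted positive fraction is exactly 0.5.
    """

    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray
    alleles: np.ndarray
    sample_weight: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    mode: str = "ensemble"

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.X) == len(self.groups) == len(self.alleles)
                == len(self.sample_weight) == n):
            raise ValueError("matrix components have inconsistent lengths")

    @property
    def n_rows(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "phla_id": self.groups,
                "allele": self.alleles,
                "label": self.y,
                "sample_weight": self.sample_weight,
            }
        )
        return pd.concat(
            [meta, pd.DataFrame(self.X, columns=self.feature_names)], axis=1
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, mode: str = "ensemble") -> "TrainingMatrix":
        feature_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
        if len(feature_cols) != N_FEATURES:
            raise ValueError(
                f"expected {N_FEATURES} feature columns, found {len(feature_cols)}"
            )
        return cls(
            X=df[feature_cols].to_numpy(dtype=float),
            y=df["label"].to_numpy(dtype=int),
            groups=df["phla_id"].to_numpy(dtype=object),
            alleles=df["allele"].to_numpy(dtype=object),
            sample_weight=df["sample_weight"].to_numpy(dtype=float),
            feature_names=feature_cols,
            mode=mode,
        )


def balanced_weights(y: np.ndarray) -> np.ndarray:
    """Per-sample weights giving each class a weighted mass of 0.5.

    With a 70:30 imbalance the per-sample weights stand in ratio 3:7
    (rarer class up-weighted); weights sum to 1.
    """
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("balanced weights need exactly two classes present")
    w = np.empty(len(y), dtype=float)
    for c in classes:
        w[y == c] = 0.5 / np.sum(y == c)
    return w


def assemble_matrix(
    examples: pd.DataFrame,
    store: ConformationStore,
    mode: str = "ensemble",
    kind: str = "sigmoid",
    steepness: float = 2.0,
) -> TrainingMatrix:
    """Featurize conformations of labeled pHLAs into a training matrix.

    ``examples`` is the output of :func:`build_labels`.  In ``ensemble``
    mode every conformation becomes a row (carrying the pHLA's label); in
    ``single`` mode only the best-scoring conformation per pHLA is used.
    Examples with zero conformations in the store are skipped with a
    warning.  Row order is deterministic: sorted by (phla_id,
    conformation_id).
    """
    if mode not in ("single", "ensemble"):
        raise ValueError(f"mode must be 'single' or 'ensemble', got {mode!r}")
    featurizer = ContactFeaturizer(kind=kind, steepness=steepness).fit([])
    rows, labels, groups, alleles = [], [], [], []
    n_skipped = 0
    for ex in examples.sort_values("phla_id").itertuples():
        try:
            confs = (
                [store.best_conformation(ex.phla_id)]
                if mode == "single"
                else store.conformations(ex.phla_id)
            )
        except (KeyError, FileNotFoundError):
            confs = []
        if not confs:
            n_skipped += 1
            logger.warning("%s: no conformations found; example skipped", ex.phla_id)
            continue
        vecs = featurizer.transform([rec for _, rec in confs])
        rows.append(vecs)
        labels.extend([ex.label] * len(confs))
        groups.extend([ex.phla_id] * len(confs))
        alleles.extend([ex.allele] * len(confs))
    if not rows:
        raise ValueError("no examples with conformations; nothing to assemble")
    y = np.asarray(labels, dtype=int)
    matrix = TrainingMatrix(
        X=np.vstack(rows),
        y=y,
        groups=np.asarray(groups, dtype=object),
        alleles=np.asarray(alleles, dtype=object),
        sample_weight=balanced_weights(y),
        mode=mode,
    )
    logger.info(
        "assembled %s matrix: %d rows, %d pHLAs, %d skipped",
        mode, matrix.n_rows, len(np.unique(matrix.groups)), n_skipped,
    )
    return matrix
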