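"""Residue-pair interaction featurization of pHLA conformations.

Every conformation is summarized as a 210-element vector, one entry per
unordered pair of the 20 standard amino acids (including same-type pairs).
For each (peptide residue, HLA residue) pair the distance is the minimum
over all heavy-atom pairs, in Å; a monotonically decreasing transform maps
it to an "amount of interaction", and amounts are summed into the entry for
that amino-acid pair type.  Peptide–peptide and HLA–HLA pairs are ignored:
only the cross-interface interactions enter the vector.

The pair ordering is lexicographic on the sorted one-letter codes —
(A,A)=0, (A,C)=1, …, (Y,Y)=209 — and is fixed for all structures.  A zero
entry means the corresponding pair type does not occur at the interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .structure import STANDARD_AAS, StructureRecord

logger = logging.getLogger(__name__)

N_FEATURES = 210

TransformKind = Literal["reciprocal", "reciprocal_squared", "sigmoid"]

#: Midpoint of the sigmoid transform: the conventional residue-contact range
#: is about 4.5–5 Å, and the sigmoid is anchored to value 0.5 at 5 Å.
SIGMOID_MIDPOINT = 5.0

#: Reciprocal transforms diverge as d -> 0; distances below this floor (Å)
#: are clamped (a genuine heavy-atom clash, never seen in valid structures).
CLASH_FLOOR = 0.1

_TRANSFORM_ALIASES = {
    "reciprocal": "reciprocal",
    "1/d": "reciprocal",
    "reciprocal_squared": "reciprocal_squared",
    "reciprocal2": "reciprocal_squared",
    "1/d2": "reciprocal_squared",
    "sigmoid": "sigmoid",
    "sig": "sigmoid",
}


def _canonical_kind(kind: str) -> str:
    try:
        return _TRANSFORM_ALIASES[kind]
    except KeyError:
        raise ValueError(
            f"unknown transform kind {kind!r}; expected one of "
            "reciprocal, reciprocal_squared, sigmoid"
        ) from None


def _build_pair_index() -> dict[tuple[str, str], int]:
    table = {}
    k = 0
    for i, a in enumerate(STANDARD_AAS):
        for b in STANDARD_AAS[i:]:
            table[(a, b)] = k
            k += 1
    return table


_PAIR_INDEX = _build_pair_index()
_INDEX_PAIR = {v: k for k, v in _PAIR_INDEX.items()}

FEATURE_NAMES = [f"f{k:03d}" for k in range(N_FEATURES)]


def pair_index(aa1: str, aa2: str) -> int:
    """Index of the unordered amino-acid pair in the 210-element vector.

    Symmetric (``pair_index(a, b) == pair_index(b, a)``) and bijective onto
    ``[0, 210)`` over unordered pairs with repetition, ordered
    lexicographically on the sorted pair: (A,A)=0, (A,C)=1, …, (Y,Y)=209.
    """
    key = (aa1, aa2) if aa1 <= aa2 else (aa2, aa1)
    try:
        return _PAIR_INDEX[key]
    except KeyError:
        raise ValueError(f"non-standard amino acid code in pair ({aa1!r}, {aa2!r})") from None


def pair_name(index: int) -> str:
    """Human-readable pair for a feature index, e.g. ``'R-D'``."""
    a, b = _INDEX_PAIR[index]
    return f"{a}-{b}"


def transform(
    d: float | np.ndarray,
    kind: str = "sigmoid",
    steepness: float = 2.0,
) -> float | np.ndarray:
    """Map a residue–residue distance (Å) to an interaction amount.

    All three transforms are strictly decreasing in ``d``:

    - ``reciprocal``: 1/d
    - ``reciprocal_squared``: 1/d²
    - ``sigmoid``: 1 / (1 + exp(steepness · (d − 5))), a logistic anchored
      so that the value is exactly 0.5 at 5 Å for any positive steepness.

    ``steepness`` (Å⁻¹) only affects the sigmoid; the default 2 Å⁻¹ puts the
    0.1–0.9 transition roughly across 3.9–6.1 Å.
    """
    kind = _canonical_kind(kind)
    arr = np.asarray(d, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("distances must be strictly positive")
    if kind == "sigmoid":
        if steepness <= 0:
            raise ValueError("sigmoid steepness must be positive")
        out = 1.0 / (1.0 + np.exp(steepness * (arr - SIGMOID_MIDPOINT)))
    else:
        clamped = np.maximum(arr, CLASH_FLOOR)
        if np.any(arr < CLASH_FLOOR):
            logger.warning(
                "%d distance(s) below the %.2f Å clash floor clamped",
                int(np.sum(arr < CLASH_FLOOR)), CLASH_FLOOR,
            )
        out = 1.0 / clamped if kind == "reciprocal" else 1.0 / clamped**2
    return float(out) if np.isscalar(d) or np.ndim(d) == 0 else out


@dataclass(frozen=True)
class ContactRecord:
    """One peptide-residue/HLA-residue pair at the interface."""

    peptide_pos: int
    peptide_aa: str
    hla_pos: int
    hla_aa: str
    distance: float        # Å, minimum over heavy-atom pairs
    transformed: float     # f(distance), unitless
    feature_index: int     # pair_index(peptide_aa, hla_aa)


@dataclass
class FeatureVector:
    """The 210-element interaction vector for one conformation."""

    values: np.ndarray
    phla_id: str = ""
    conformation_id: str = ""
    allele: str = ""
    label: int | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("feature values must be finite and non-negative")
        self.values = vals


def compute_contacts(
    record: StructureRecord,
    kind: str = "sigmoid",
    steepness: float = 2.0,
    cutoff: float | None = None,
) -> list[ContactRecord]:
    """All (peptide residue, HLA residue) contacts of a conformation.

    One record per cross-interface residue pair; the distance is the minimum
    heavy-atom distance.  ``cutoff`` (Å) optionally drops pairs farther than
    the cutoff (off by default: every pair contributes and the transforms
    decay naturally).
    """
    kind = _canonical_kind(kind)
    contacts: list[ContactRecord] = []
    for pep in record.peptide_residues:
        for hla in record.hla_residues:
            d = float(cdist(pep.heavy_atoms, hla.heavy_atoms).min())
            if cutoff is not None and d > cutoff:
                continue
            contacts.append(
                ContactRecord(
                    peptide_pos=pep.position,
                    peptide_aa=pep.aa,
                    hla_pos=hla.position,
                    hla_aa=hla.aa,
                    distance=d,
                    transformed=float(transform(d, kind, steepness)),
                    feature_index=pair_index(pep.aa, hla.aa),
                )
            )
    return contacts


def featurize(
    record: StructureRecord,
    kind: str = "sigmoid",
    steepness: float = 2.0,
    cutoff: float | None = None,
) -> FeatureVector:
    """Sum transformed contact amounts into the 210-element vector."""
    contacts = compute_contacts(record, kind, steepness, cutoff)
    return vector_from_contacts(record, contacts)


def vector_from_contacts(
    record: StructureRecord, contacts: Sequence[ContactRecord]
) -> FeatureVector:
    values = np.zeros(N_FEATURES)
    for c in contacts:
        values[c.feature_index] += c.transformed
    return FeatureVector(
        values=values,
        phla_id=record.phla_id,
        conformation_id=record.conformation_id,
    )


class ContactFeaturizer(BaseEstimator, TransformerMixin):
    """Transformer from pHLA structures to interaction feature matrices.

    A stateless scikit-learn transformer: ``fit`` is a no-op and
    ``transform`` maps a sequence of :class:`StructureRecord` to an
    ``(n, 210)`` array.

    Parameters
    ----------
    kind : {"reciprocal", "reciprocal_squared", "sigmoid"}
        Distance transform applied to the minimum heavy-atom distances.
    steepness : float
        Sigmoid steepness in Å⁻¹ (ignored by the reciprocal transforms).
    cutoff : float or None
        Optional contact cutoff in Å; by default all residue pairs count.
    """

    def __init__(
        self,
        kind: str = "sigmoid",
        steepness: float = 2.0,
        cutoff: float | None = None,
    ):
        self.kind = kind
        self.steepness = steepness
        self.cutoff = cutoff

    def fit(self, X: Iterable[StructureRecord], y=None):
        _canonical_kind(self.kind)
        self.n_features_out_ = N_FEATURES
        return self

    def transform(self, X: Iterable[StructureRecord]) -> np.ndarray:
        return np.vstack(
            [
                featurize(rec, self.kind, self.steepness, self.cutoff).values
                for rec in X
            ]
        )

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)


def vectors_to_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabulate feature vectors: metadata columns + f000..f209."""
    meta = pd.DataFrame(
        {
            "phla_id": [v.phla_id for v in vectors],
            "conformation_id": [v.conformation_id for v in vectors],
            "allele": [v.allele for v in vectors],
            "label": [v.label for v in vectors],
        }
    )
    values = pd.DataFrame(
        np.vstack([v.values for v in vectors]), columns=FEATURE_NAMES
    )
    return pd.concat([meta, values], axis=1)


def contacts_to_frame(contacts: Sequence[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contacts])
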