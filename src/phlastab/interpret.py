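"""Decision-path contribution decomposition for forest predictions.

A random forest's predicted probability of stable binding can be rewritten
exactly as

    P(x) = bias + Σ_j contrib_j(x),          j over the 210 pair features

by walking, in each tree, the root-to-leaf path of the example: every
traversed split transfers probability mass (child node's positive-class
fraction minus its parent's) to the feature split on, and the tree's bias
is its root positive-class fraction.  Forest-level quantities are means
across trees.  Under balanced class reweighting the bias is 0.5 (exactly so
when bootstrapping is disabled).

Because each feature value is itself a linear sum of transformed contact
amounts, every feature's contribution can be pushed further down onto the
individual peptide–HLA residue contacts that produced it, proportionally to
each contact's share of the feature value.  Contributions can then be
re-aggregated by peptide position or by anchor status (positions 2 and the
C-terminus by default), giving a per-prediction account of which contacts
argued for or against stable binding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .featurize import ContactRecord, FeatureVector, N_FEATURES, pair_name
from .models import StablePeptideClassifier

logger = logging.getLogger(__name__)

_ATOL = 1e-9


def _forest_of(model) -> RandomForestClassifier:
    if isinstance(model, StablePeptideClassifier):
        if model.model != "rf":
            raise ValueError(
                "path decomposition requires a random forest; "
                f"got model kind {model.model!r}"
            )
        forest = model.estimator_
    else:
        forest = model
    if not isinstance(forest, RandomForestClassifier):
        raise ValueError("expected a fitted random forest")
    return forest


def _tree_decompose(tree, x: np.ndarray, positive: int) -> tuple[float, np.ndarray]:
    """Walk one tree's decision path; return (bias, per-feature contribs)."""
    t = tree.tree_
    # node values are weighted class fractions summing to 1 per node
    values = t.value[:, 0, positive]
    contribs = np.zeros(len(x))
    node = 0
    bias = float(values[0])
    while t.children_left[node] != -1:  # not a leaf
        feat = t.feature[node]
        child = (
            t.children_left[node]
            if x[feat] <= t.threshold[node]
            else t.children_right[node]
        )
        contribs[feat] += values[child] - values[node]
        node = child
    return bias, contribs


def decompose_prediction(
    model, x: FeatureVector | np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Exact additive decomposition of a forest prediction.

    Returns ``(bias, feature_contribs, P)`` with
    ``bias + feature_contribs.sum() == P`` to machine precision, where ``P``
    is the forest's predicted positive-class probability for ``x``.
    """
    forest = _forest_of(model)
    vec = x.values if isinstance(x, FeatureVector) else np.asarray(x, dtype=float)
    if vec.shape != (forest.n_features_in_,):
        raise ValueError(
            f"feature vector has length {vec.shape}, model expects "
            f"{forest.n_features_in_}"
        )
    positive = int(np.flatnonzero(forest.classes_ == 1)[0])
    biases = np.empty(len(forest.estimators_))
    contribs = np.zeros((len(forest.estimators_), len(vec)))
    for i, tree in enumerate(forest.estimators_):
        biases[i], contribs[i] = _tree_decompose(tree, vec, positive)
    bias = float(biases.mean())
    feature_contribs = contribs.mean(axis=0)
    p = float(forest.predict_proba(vec[None, :])[0, positive])
    residual = abs(bias + feature_contribs.sum() - p)
    if residual > 1e-6:
        raise AssertionError(
            f"decomposition does not reproduce the prediction (residual {residual:.2e})"
        )
    return bias, feature_contribs, p


def allocate_contacts(
    feature_contribs: np.ndarray,
    contacts: Sequence[ContactRecord],
    on_missing: str = "raise",
) -> np.ndarray:
    """Distribute feature contributions onto individual contacts.

    Contact ``c`` with feature index ``j`` receives
    ``contrib_j * transformed(c) / value_j``, where ``value_j`` is the sum
    of transformed amounts over the feature's contacts — the unique linear,
    conservative, permutation-symmetric allocation.

    ``on_missing`` governs contributions on features without any contact.
    With ``"raise"`` (default) they are a hard error — the right check when
    the contacts are supposed to be exactly the ones ``x`` was built from
    and every pair type with contribution should be present.  With
    ``"ignore"`` they are left unallocated: trees do split on pair types
    absent from a structure (the split "feature ≤ threshold" is satisfied
    at zero), and that absent-pair contribution has no contact to carry it.
    :func:`summarize` reports it separately so conservation still closes.
    """
    if on_missing not in ("raise", "ignore"):
        raise ValueError("on_missing must be 'raise' or 'ignore'")
    feature_contribs = np.asarray(feature_contribs, dtype=float)
    values = np.zeros(len(feature_contribs))
    for c in contacts:
        values[c.feature_index] += c.transformed
    orphaned = (values == 0) & (np.abs(feature_contribs) > _ATOL)
    if orphaned.any() and on_missing == "raise":
        bad = [pair_name(int(j)) for j in np.flatnonzero(orphaned)]
        raise ValueError(
            f"nonzero contribution on zero-valued feature(s) {bad}: "
            "contacts do not match the decomposed vector"
        )
    out = np.empty(len(contacts))
    for i, c in enumerate(contacts):
        v = values[c.feature_index]
        out[i] = 0.0 if v == 0 else feature_contribs[c.feature_index] * c.transformed / v
    return out


def default_anchor_positions(peptide_length: int) -> frozenset[int]:
    """Canonical Class-I anchors: position 2 and the C-terminal position."""
    return frozenset({2, peptide_length})


@dataclass
class ContributionReport:
    """Per-prediction contribution account for one conformation.

    ``positive share`` of a contact set is its summed positive
    contributions divided by all positive contributions; negative shares
    are analogous (on absolute values).  ``anchor_share`` is the positive
    share of contacts touching the anchor positions.
    """

    phla_id: str
    conformation_id: str
    prediction: float
    bias: float
    feature_contribs: np.ndarray
    contacts: list[ContactRecord]
    contact_contribs: np.ndarray
    anchor_positions: frozenset[int]
    position_summary: dict[int, dict[str, float]] = field(default_factory=dict)
    anchor_share: float = float("nan")
    anchor_share_negative: float = float("nan")
    feature_positive_shares: dict[str, float] = field(default_factory=dict)
    absent_feature_contrib: float = 0.0
    classified_stable: bool = False
    degenerate: bool = False

    def top_features(self, n: int = 10) -> list[tuple[str, float]]:
        order = np.argsort(-np.abs(self.feature_contribs))[:n]
        return [(pair_name(int(j)), float(self.feature_contribs[j])) for j in order]

    def to_dict(self) -> dict:
        return {
            "phla_id": self.phla_id,
            "conformation_id": self.conformation_id,
            "prediction": self.prediction,
            "classified_stable": self.classified_stable,
            "bias": self.bias,
            "conservation_residual": float(
                self.bias + self.feature_contribs.sum() - self.prediction
            ),
            "absent_feature_contrib": self.absent_feature_contrib,
            "anchor_positions": sorted(self.anchor_positions),
            "anchor_share": self.anchor_share,
            "anchor_share_negative": self.anchor_share_negative,
            "position_summary": {
                str(k): v for k, v in sorted(self.position_summary.items())
            },
            "top_features": [
                {"pair": p, "contribution": c} for p, c in self.top_features()
            ],
            "feature_positive_shares": self.feature_positive_shares,
            "contacts": [
                {
                    "peptide_pos": c.peptide_pos,
                    "peptide_aa": c.peptide_aa,
                    "hla_pos": c.hla_pos,
                    "hla_aa": c.hla_aa,
                    "distance": c.distance,
                    "transformed": c.transformed,
                    "pair": pair_name(c.feature_index),
                    "contribution": float(self.contact_contribs[i]),
                }
                for i, c in enumerate(self.contacts)
            ],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        lines = [
            f"pHLA {self.phla_id} conformation {self.conformation_id}",
            f"P(stable) = {self.prediction:.4f}  "
            f"({'stable' if self.classified_stable else 'unstable'}; bias {self.bias:.4f})",
            f"anchor positions {sorted(self.anchor_positions)}: "
            f"{self.anchor_share:.1%} of positive contributions"
            + ("" if np.isnan(self.anchor_share_negative)
               else f", {self.anchor_share_negative:.1%} of negative"),
            "top features (pair: contribution):",
        ]
        lines += [f"  {p:>5s}: {c:+.4f}" for p, c in self.top_features()]
        lines.append("per-position totals (pos: +sum / -sum):")
        for pos, d in sorted(self.position_summary.items()):
            lines.append(f"  {pos:3d}: {d['positive']:+.4f} / {-d['negative']:+.4f}")
        return "\n".join(lines)


def summarize(
    phla_id: str,
    conformation_id: str,
    prediction: float,
    bias: float,
    feature_contribs: np.ndarray,
    contacts: Sequence[ContactRecord],
    contact_contribs: np.ndarray,
    anchor_positions: Sequence[int] | None = None,
) -> ContributionReport:
    """Aggregate contact contributions by peptide position and anchor set.

    Shares are fractions of the total positive (resp. negative)
    contribution mass over contacts.  When every contribution is zero the
    shares are undefined and the report is flagged ``degenerate``.
    """
    contact_contribs = np.asarray(contact_contribs, dtype=float)
    if len(contact_contribs) != len(contacts):
        raise ValueError("one contribution per contact required")
    peptide_positions = sorted({c.peptide_pos for c in contacts})
    if anchor_positions is None:
        anchors = default_anchor_positions(max(peptide_positions, default=0))
    else:
        anchors = frozenset(int(p) for p in anchor_positions)

    pos_mask = contact_contribs > 0
    neg_mask = contact_contribs < 0
    total_pos = float(contact_contribs[pos_mask].sum())
    total_neg = float(-contact_contribs[neg_mask].sum())
    degenerate = total_pos == 0 and total_neg == 0
    if degenerate:
        logger.warning(
            "%s/%s: all contributions zero; shares undefined",
            phla_id, conformation_id,
        )

    position_summary: dict[int, dict[str, float]] = {}
    for p in peptide_positions:
        on_p = np.asarray([c.peptide_pos == p for c in contacts])
        position_summary[p] = {
            "positive": float(contact_contribs[on_p & pos_mask].sum()),
            "negative": float(-contact_contribs[on_p & neg_mask].sum()),
            "positive_share": (
                float(contact_contribs[on_p & pos_mask].sum() / total_pos)
                if total_pos > 0 else float("nan")
            ),
            "negative_share": (
                float(-contact_contribs[on_p & neg_mask].sum() / total_neg)
                if total_neg > 0 else float("nan")
            ),
        }

    on_anchor = np.asarray([c.peptide_pos in anchors for c in contacts])
    anchor_share = (
        float(contact_contribs[on_anchor & pos_mask].sum() / total_pos)
        if total_pos > 0 else float("nan")
    )
    anchor_share_neg = (
        float(-contact_contribs[on_anchor & neg_mask].sum() / total_neg)
        if total_neg > 0 else float("nan")
    )

    # feature-level positive shares (the same summary at feature granularity)
    fc = np.asarray(feature_contribs, dtype=float)
    present = {c.feature_index for c in contacts}
    absent_contrib = float(
        sum(fc[j] for j in range(len(fc)) if j not in present)
    )
    fpos = fc[fc > 0].sum()
    feature_positive_shares = (
        {
            pair_name(int(j)): float(fc[j] / fpos)
            for j in np.flatnonzero(fc > 0)
        }
        if fpos > 0 else {}
    )

    return ContributionReport(
        phla_id=phla_id,
        conformation_id=conformation_id,
        prediction=float(prediction),
        bias=float(bias),
        feature_contribs=np.asarray(feature_contribs, dtype=float),
        contacts=list(contacts),
        contact_contribs=contact_contribs,
        anchor_positions=anchors,
        position_summary=position_summary,
        anchor_share=anchor_share,
        anchor_share_negative=anchor_share_neg,
        feature_positive_shares=feature_positive_shares,
        absent_feature_contrib=absent_contrib,
        classified_stable=float(prediction) >= 0.5,
        degenerate=degenerate,
    )


def explain_conformation(
    model,
    record,
    kind: str = "sigmoid",
    steepness: float = 2.0,
    anchor_positions: Sequence[int] | None = None,
) -> ContributionReport:
    """End-to-end explanation of one conformation's prediction."""
    from .featurize import compute_contacts, vector_from_contacts

    contacts = compute_contacts(record, kind, steepness)
    x = vector_from_contacts(record, contacts)
    bias, feature_contribs, p = decompose_prediction(model, x)
    contact_contribs = allocate_contacts(feature_contribs, contacts, on_missing="ignore")
    return summarize(
        record.phla_id, record.conformation_id, p, bias,
        feature_contribs, contacts, contact_contribs, anchor_positions,
    )


def explain_phla(
    model,
    records: Sequence,
    kind: str = "sigmoid",
    steepness: float = 2.0,
    anchor_positions: Sequence[int] | None = None,
) -> tuple[list[ContributionReport], dict]:
    """Explain every conformation of a pHLA and average the decomposition.

    The averaged decomposition is consistent with ensemble probability
    averaging: mean bias + summed mean contributions = mean P.
    """
    if not records:
        raise ValueError("need at least one conformation")
    reports = [
        explain_conformation(model, rec, kind, steepness, anchor_positions)
        for rec in records
    ]
    mean_contribs = np.mean([r.feature_contribs for r in reports], axis=0)
    averaged = {
        "phla_id": reports[0].phla_id,
        "n_conformations": len(reports),
        "prediction": float(np.mean([r.prediction for r in reports])),
        "bias": float(np.mean([r.bias for r in reports])),
        "feature_contribs": mean_contribs.tolist(),
        "anchor_share": float(np.nanmean([r.anchor_share for r in reports])),
    }
    return reports, averaged
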