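"""Recovery metrics: inferred families vs planted truth."""

from __future__ import annotations

from typing import Sequence

from sklearn.metrics import adjusted_rand_score

from .mcl import OrthologFamily
from .simulate import SyntheticTruth


def family_labels(families: Sequence[OrthologFamily]) -> dict[str, str]:
    return {g: f.family_id for f in families for g in f.members}


def clustering_ari(families: Sequence[OrthologFamily], truth: SyntheticTruth) -> float:
    """Adjusted Rand index between inferred and planted partitions.

    Planted singletons each count as their own cluster.
    """
    pred = family_labels(families)
    genes = sorted(truth.gene_to_family)
    missing = [g for g in genes if g not in pred]
    if missing:
        raise ValueError(f"{len(missing)} genes missing from inferred families")
    true_labels = truth.labels(genes)
    pred_labels = [pred[g] for g in genes]
    return float(adjusted_rand_score(true_labels, pred_labels))


def exact_recovery_rate(
    families: Sequence[OrthologFamily], truth: SyntheticTruth
) -> float:
    """Fraction of planted families recovered as identical member sets."""
    planted = {frozenset(f.members) for f in truth.families.values()}
    inferred = {frozenset(f.members) for f in families}
    if not planted:
        return 1.0
    return len(planted & inferred) / len(planted)


def match_family_ids(
    families: Sequence[OrthologFamily], planted_ids: Sequence[str],
    truth: SyntheticTruth,
) -> dict[str, str | None]:
    """Map planted family ids to the inferred family id with the same members."""
    inferred = {frozenset(f.members): f.family_id for f in families}
    return {
        fid: inferred.get(frozenset(truth.families[fid].members))
        for fid in planted_ids
    }
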