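"""Scoring reconstructions against a known community.

Three evaluations: (i) abundance recovery — reconstructions are matched
1:1 to truth sequences by global-alignment identity (97% floor, the
usual OTU level) and the Pearson correlation between estimated priors
and expected abundances is computed over all truth members; (ii) N50 of
reconstructed sequence lengths; (iii) weighted UniFrac between the
reconstructed and expected communities on a user-supplied rooted tree,
raw (sum over branches of branch length times the absolute difference
in subtree abundance mass) and normalized by the abundance-weighted
maximum, with a seeded leaf-label permutation test for significance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import identity_ungapped

__all__ = [
    "AbundanceComparison",
    "match_and_correlate",
    "n50",
    "weighted_unifrac",
    "unifrac_permutation_test",
]

OTU_IDENTITY_FLOOR = 0.97


@dataclass
class AbundanceComparison:
    """Matched truth/reconstruction abundances and the correlation over them."""

    pairs: pd.DataFrame  # truth_name, reconstructed_id, truth_abund, estimated_prior, identity
    novel: list[str]  # reconstruction ids below the identity floor
    pearson_r: float
    p_value: float


def match_and_correlate(
    truth_profile: dict[str, float],
    truth_seqs: dict[str, str],
    reconstructions: Sequence[tuple[str, str, float]],
    identity_floor: float = OTU_IDENTITY_FLOOR,
) -> AbundanceComparison:
    """Match reconstructions to truth sequences and correlate abundances.

    ``reconstructions`` is a sequence of (id, sequence, prior).  Each
    reconstruction is matched to its best-identity truth sequence,
    greedily by identity so that each truth member is matched by at most
    one reconstruction and vice versa; reconstructions below
    ``identity_floor`` are reported as novel.  Unmatched truth members
    get estimated abundance 0, and Pearson r is computed over all truth
    members.
    """
    names = list(truth_profile)
    if len(names) < 3:
        raise ValueError("need at least 3 truth members for a correlation")
    candidates = []
    for rid, seq, prior in reconstructions:
        for name in names:
            ident = identity_ungapped(seq, truth_seqs[name])
            if ident >= identity_floor:
                candidates.append((ident, rid, name, prior))
    candidates.sort(key=lambda t: -t[0])
    matched_truth: dict[str, tuple[str, float, float]] = {}
    matched_recon: set[str] = set()
    for ident, rid, name, prior in candidates:
        if name in matched_truth or rid in matched_recon:
            continue
        matched_truth[name] = (rid, prior, ident)
        matched_recon.add(rid)
    novel = [rid for rid, _, _ in reconstructions if rid not in matched_recon]
    rows = []
    for name in names:
        rid, prior, ident = matched_truth.get(name, (None, 0.0, np.nan))
        rows.append(
            {
                "truth_name": name,
                "reconstructed_id": rid,
                "truth_abund": truth_profile[name],
                "estimated_prior": prior,
                "identity": ident,
            }
        )
    table = pd.DataFrame(rows)
    x = table["truth_abund"].to_numpy()
    y = table["estimated_prior"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in abundances: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return AbundanceComparison(table, novel, float(r), float(p))


def n50(lengths: Sequence[int]) -> int:
    """Largest L with at least half the total length in sequences >= L."""
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        raise ValueError("n50 of an empty length set")
    half = sum(lengths) / 2.0
    acc = 0
    for L in reversed(lengths):
        acc += L
        if acc >= half:
            return L
    return lengths[0]  # pragma: no cover


def _leaf_masses(tree, profile: dict[str, float], label: str) -> None:
    seen = set()
    for node in tree.postorder():
        if node.is_tip():
            mass = profile.get(node.name, 0.0)
            seen.add(node.name)
            setattr(node, label, mass)
        else:
            setattr(
                node, label, sum(getattr(ch, label) for ch in node.children)
            )
    missing = set(profile) - seen
    if missing:
        raise ValueError(
            f"profile taxa missing from the tree: {sorted(missing)}"
        )


def weighted_unifrac(
    tree,
    profile_a: dict[str, float],
    profile_b: dict[str, float],
    normalized: bool = True,
) -> float:
    """Weighted UniFrac distance between two communities on a rooted tree.

    ``tree`` is an ``skbio.TreeNode`` (or any object with the same
    ``postorder``/``tip`` interface) with branch lengths; profiles put
    abundance mass on tip names and should each sum to 1.  The raw
    distance is ``sum_b len_b * |A_b - B_b|`` with ``A_b`` the fraction
    of profile A under branch ``b``; the normalized variant divides by
    the abundance-weighted maximum ``sum_i (A_i + B_i) * depth_i``.
    """
    for profile in (profile_a, profile_b):
        total = sum(profile.values())
        if total > 0 and not np.isclose(total, 1.0):
            raise ValueError("profiles must sum to 1")
    _leaf_masses(tree, profile_a, "_mass_a")
    _leaf_masses(tree, profile_b, "_mass_b")
    raw = 0.0
    for node in tree.postorder():
        if node.parent is None:
            continue
        length = node.length or 0.0
        raw += length * abs(node._mass_a - node._mass_b)
    if not normalized:
        return raw
    denom = 0.0
    for tip in tree.tips():
        depth = 0.0
        node = tip
        while node.parent is not None:
            depth += node.length or 0.0
            node = node.parent
        denom += (
            profile_a.get(tip.name, 0.0) + profile_b.get(tip.name, 0.0)
        ) * depth
    if denom == 0.0:
        return 0.0
    return raw / denom


def unifrac_permutation_test(
    tree,
    profile_a: dict[str, float],
    profile_b: dict[str, float],
    n_permutations: int = 1000,
    normalized: bool = True,
    seed: int = 0,
) -> tuple[float, float]:
    """Leaf-label permutation test for the weighted UniFrac distance.

    Returns (observed distance, p-value): the fraction of label
    permutations of profile B whose distance is <= the observed one
    would indicate similarity; here p is the fraction of permutations
    with distance <= observed (small p means the two communities are
    more similar than random labelings).
    """
    rng = np.random.default_rng(seed)
    observed = weighted_unifrac(tree, profile_a, profile_b, normalized)
    tips = [t.name for t in tree.tips()]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(tips))
        shuffled = {
            tips[perm[i]]: profile_b.get(tips[i], 0.0) for i in range(len(tips))
        }
        d = weighted_unifrac(tree, profile_a, shuffled, normalized)
        if d <= observed:
            count += 1
    return observed, count / n_permutations
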