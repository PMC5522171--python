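"""Rule-based prescription assembly.

The formula is ``prescription = hub CM pair + alternative CMs``: an
anchor pair of herbs jointly inducing disease-related synthetic lethality,
extended with alternatives chosen by (i) category preference — tonic (3),
hemorheologic (6), exterior-releasing (1), in that order, with a soft cap
so no category dominates the decoction — (ii) greedy marginal gain in the
union of DEG targets, and (iii) matches to the patient's clinical feature
tags. The greedy-with-tiers rule is this package's operationalization of a
qualitative clinical heuristic and is documented as such in the methods
note.

``extend_decoction`` handles the classical-decoction modification case:
given an existing base formula, pick the hub CM that forms an SL-inducing
pair with one of the base herbs, drawn from a category not already
saturated in the base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import (
    Dict,
    FrozenSet,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
)

from .mapping import HerbTargetProfile
from .sl import HerbPairReport
from .types import HerbnetError, HerbRecord

logger = logging.getLogger(__name__)

__all__ = [
    "PatientProfile",
    "Prescription",
    "build_prescription",
    "extend_decoction",
    "derive_variants",
    "format_prescription",
    "PREFERRED_CATEGORIES",
]

#: Category preference order for alternatives: tonic, hemorheologic,
#: exterior-releasing — the three groups with the highest mean DEG-target
#: coverage.
PREFERRED_CATEGORIES: Tuple[int, ...] = (3, 6, 1)

DEFAULT_MAX_PER_CATEGORY = 3


@dataclass(frozen=True)
class PatientProfile:
    """Clinical feature tags (normalized lower-case) and optional molecular
    tags (gene symbols of interest)."""

    feature_tags: FrozenSet[str] = frozenset()
    molecular_tags: FrozenSet[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self,
            "feature_tags",
            frozenset(str(t).strip().lower() for t in self.feature_tags if str(t).strip()),
        )
        object.__setattr__(
            self,
            "molecular_tags",
            frozenset(str(t).strip().upper() for t in self.molecular_tags if str(t).strip()),
        )


@dataclass(frozen=True)
class Prescription:
    """An assembled prescription with per-herb rationale tags."""

    hub_pair: Tuple[str, str]
    alternatives: Tuple[str, ...]
    rationale: Mapping[str, str]  # herb_id -> hub | group-preference | feature-match
    total_deg_targets: int
    deg_targets: FrozenSet[str] = frozenset()
    base_herbs: Tuple[str, ...] = ()
    feature_tag: Optional[str] = None

    @property
    def members(self) -> Tuple[str, ...]:
        seen: List[str] = []
        for h in (*self.base_herbs, *self.hub_pair, *self.alternatives):
            if h not in seen:
                seen.append(h)
        return tuple(seen)


def _union_targets(
    members: Sequence[str], profiles: Mapping[str, HerbTargetProfile]
) -> FrozenSet[str]:
    out: Set[str] = set()
    for h in members:
        prof = profiles.get(h)
        if prof is not None:
            out |= prof.targeted_degs
    return frozenset(out)


def _pair_sort_key(rep: HerbPairReport):
    return (-rep.safety_ratio, -len(rep.covered_aml_pairs), (rep.herb_1, rep.herb_2))


def _category_counts(members: Sequence[str], by_id: Mapping[str, HerbRecord]) -> Dict[int, int]:
    counts: Dict[int, int] = {}
    for h in members:
        herb = by_id.get(h)
        if herb is not None:
            counts[herb.category] = counts.get(herb.category, 0) + 1
    return counts


def extend_decoction(
    base_herbs: Sequence[str],
    hub_pairs: Sequence[HerbPairReport],
    profiles: Mapping[str, HerbTargetProfile],
    herb_table: Sequence[HerbRecord],
    max_per_category: int = DEFAULT_MAX_PER_CATEGORY,
) -> Tuple[str, str]:
    """Choose a hub CM extension for an existing decoction.

    Candidates are herbs outside the base that form an SL-inducing pair
    with a base herb. Candidates whose category already holds
    ``max_per_category`` base herbs are deferred (used only if no
    unsaturated candidate exists). Ties break by DEG-target count
    descending, then Latin name. Returns (base partner, extension).
    """
    base = list(base_herbs)
    by_id = {h.herb_id: h for h in herb_table}
    cat_counts = _category_counts(base, by_id)
    candidates: List[Tuple[bool, int, str, str, str]] = []
    for rep in hub_pairs:
        for partner, ext in ((rep.herb_1, rep.herb_2), (rep.herb_2, rep.herb_1)):
            if partner in base and ext not in base:
                herb = by_id.get(ext)
                if herb is None:
                    continue
                saturated = cat_counts.get(herb.category, 0) >= max_per_category
                n_targets = profiles[ext].n_targets if ext in profiles else 0
                candidates.append((saturated, -n_targets, herb.latin_name, ext, partner))
    if not candidates:
        raise HerbnetError("no hub CM pairs a member of the base decoction")
    saturated, _, _, ext, partner = min(candidates)
    if saturated:
        logger.warning("all extension candidates come from saturated categories")
    return partner, ext


def _choose_alternatives(
    k: int,
    members: List[str],
    profiles: Mapping[str, HerbTargetProfile],
    by_id: Mapping[str, HerbRecord],
    patient: PatientProfile,
    feature_rules: Mapping[str, Sequence[str]],
    max_per_category: int,
) -> Tuple[List[str], Dict[str, str]]:
    feature_herbs: Set[str] = set()
    for tag in patient.feature_tags:
        feature_herbs.update(feature_rules.get(tag, ()))
    chosen: List[str] = []
    rationale: Dict[str, str] = {}
    current = set(members)
    union = set(_union_targets(members, profiles))
    for _ in range(k):
        cat_counts = _category_counts(list(current), by_id)
        best = None
        for hid, herb in by_id.items():
            if hid in current or herb.excluded:
                continue
            if herb.category in PREFERRED_CATEGORIES:
                tier = PREFERRED_CATEGORIES.index(herb.category)
            else:
                tier = len(PREFERRED_CATEGORIES)
            if cat_counts.get(herb.category, 0) >= max_per_category:
                tier = len(PREFERRED_CATEGORIES) + 1  # saturated: last resort
            prof = profiles.get(hid)
            gain = len(prof.targeted_degs - union) if prof is not None else 0
            is_feature = hid in feature_herbs
            key = (tier, -gain, not is_feature, herb.latin_name, hid)
            if best is None or key < best[0]:
                best = (key, hid, is_feature, prof)
        if best is None:
            break
        _, hid, is_feature, prof = best
        chosen.append(hid)
        rationale[hid] = "feature-match" if is_feature else "group-preference"
        current.add(hid)
        if prof is not None:
            union |= prof.targeted_degs
    return chosen, rationale


def build_prescription(
    hub_pairs: Sequence[HerbPairReport],
    profiles: Mapping[str, HerbTargetProfile],
    herb_table: Sequence[HerbRecord],
    patient: PatientProfile,
    k_alternatives: int,
    feature_rules: Optional[Mapping[str, Sequence[str]]] = None,
    base_herbs: Sequence[str] = (),
    max_per_category: int = DEFAULT_MAX_PER_CATEGORY,
) -> Prescription:
    """Assemble a prescription around the best hub CM pair.

    The anchor pair maximizes the safety ratio, ties broken by number of
    disease SL pairs covered, then lexicographically — deterministic given
    inputs. With ``base_herbs`` (decoction modification) the anchor is the
    base plus the extension chosen by :func:`extend_decoction`.
    """
    if not hub_pairs:
        raise HerbnetError("no hub CM pairs available; cannot form a prescription")
    feature_rules = feature_rules or {}
    by_id = {h.herb_id: h for h in herb_table}
    rationale: Dict[str, str] = {}
    if base_herbs:
        partner, ext = extend_decoction(
            base_herbs, hub_pairs, profiles, herb_table, max_per_category
        )
        pair = (partner, ext)
        rationale[ext] = "hub"
        for h in base_herbs:
            rationale.setdefault(h, "base")
    else:
        best = min(hub_pairs, key=_pair_sort_key)
        pair = (best.herb_1, best.herb_2)
        rationale[pair[0]] = rationale[pair[1]] = "hub"
    members = list(dict.fromkeys([*base_herbs, *pair]))
    alternatives, alt_rationale = _choose_alternatives(
        k_alternatives, members, profiles, by_id, patient, feature_rules, max_per_category
    )
    rationale.update(alt_rationale)
    all_members = members + alternatives
    targets = _union_targets(all_members, profiles)
    return Prescription(
        hub_pair=pair,
        alternatives=tuple(alternatives),
        rationale=rationale,
        total_deg_targets=len(targets),
        deg_targets=targets,
        base_herbs=tuple(base_herbs),
    )


def derive_variants(
    base: Prescription,
    feature_rules: Mapping[str, Sequence[str]],
    profiles: Optional[Mapping[str, HerbTargetProfile]] = None,
) -> List[Prescription]:
    """One variant per clinical feature tag: the first rule candidate not
    already in the prescription is appended with a feature-match rationale.
    Features with no available candidate yield no variant (warned)."""
    profiles = profiles or {}
    variants: List[Prescription] = []
    members = set(base.members)
    for tag in sorted(feature_rules):
        candidate = next((h for h in feature_rules[tag] if h not in members), None)
        if candidate is None:
            logger.warning("feature %r: no candidate herb available; no variant", tag)
            continue
        targets = set(base.deg_targets)
        prof = profiles.get(candidate)
        if prof is not None:
            targets |= prof.targeted_degs
        rationale = dict(base.rationale)
        rationale[candidate] = "feature-match"
        variants.append(
            Prescription(
                hub_pair=base.hub_pair,
                alternatives=(*base.alternatives, candidate),
                rationale=rationale,
                total_deg_targets=len(targets),
                deg_targets=frozenset(targets),
                base_herbs=base.base_herbs,
                feature_tag=tag,
            )
        )
    return variants


def format_prescription(
    prescription: Prescription, herb_table: Sequence[HerbRecord]
) -> str:
    """Deterministic plain-text rendering (byte-identical across runs)."""
    latin = {h.herb_id: h.latin_name for h in herb_table}
    lines = []
    if prescription.feature_tag:
        lines.append(f"# variant for clinical feature: {prescription.feature_tag}")
    lines.append(
        "hub pair: "
        + " + ".join(f"{h} ({latin.get(h, '?')})" for h in prescription.hub_pair)
    )
    if prescription.base_herbs:
        lines.append(
            "base decoction: "
            + ", ".join(f"{h} ({latin.get(h, '?')})" for h in prescription.base_herbs)
        )
    for h in prescription.alternatives:
        lines.append(
            f"alternative: {h} ({latin.get(h, '?')}) [{prescription.rationale.get(h, '')}]"
        )
    lines.append(f"total DEG targets covered: {prescription.total_deg_targets}")
    return "\n".join(lines) + "\n"
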