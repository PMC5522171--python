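"""Seeded synthetic-data generator with planted, recoverable structure.

The generator emulates the statistical shape of the six input resources —
a degree-skewed PPI background (preferential attachment), confidence-
scored bipartite chemical–protein links (background scores below the 0.9
decision boundary, planted links above it), multi-ingredient herbs with
the eight-category label distribution, confidence/disease-tagged SL pairs,
and a pathway database with a planted shared/unique block structure — and
records every planted fact in a ground-truth manifest so each pipeline
stage can be checked for exact recovery.

Planting is constructive, not statistical, wherever a stage must recover
it exactly: hub DEGs are wired to at least the hub-threshold number of
distinct partners while all other DEG products stay strictly below it
(DEG–DEG edges are never drawn, so DEG degrees are exactly as planted);
SL-pair genes receive high-confidence links only through dedicated
compounds held by the designated covering herbs; pathway gene pools are
private per category. Background noise (random links, random ingredients,
random SL pairs) never touches those reserved genes and compounds.

The default configuration mirrors the study conditions: 596 DEGs (290 up,
306 down), 43 curated key proteins, 149 DEGs with no network match, 197
DEG products at degree >= 25 (86 up / 111 down) covering 31 keys plus 12
sub-threshold keys, a flagship tonic herb reaching 83 DEG targets (37 up /
46 down), 2 high-confidence (+3 low-confidence) AML SL pairs, 5 covering
herbs, and a pathway structure with a 35-pathway shared core inside a
union of 208. The PPI background is scaled to 1,200 partner proteins.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Dict, FrozenSet, List, Sequence, Tuple

import networkx as nx
import numpy as np

from . import io as hio
from .types import (
    ChemicalProteinLink,
    ConfigError,
    GeneRecord,
    HerbRecord,
    InteractionNetwork,
    PathwayAnnotation,
    SLPairRecord,
)

__all__ = ["GeneratorConfig", "SyntheticBundle", "generate"]

_NON_AML_TAGS = ("BRCA", "LUAD", "GBM")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    seed: int = 0

    # DEG table
    n_deg_up: int = 290
    n_deg_down: int = 306
    n_key: int = 43
    n_unmatched: int = 149

    # hub planting
    n_planted_hubs: int = 197
    n_hub_up: int = 86
    n_keys_in_hubs: int = 31
    hub_threshold: int = 25
    hub_degree_max: int = 60

    # PPI background
    n_partners: int = 1200
    pa_m: int = 3

    # flagship herb (top DEG-target coverage)
    n_flagship_up: int = 37
    n_flagship_down: int = 46
    n_flagship_compounds: int = 10

    # hub-gene allocation for pathways / SL / general links
    n_pathway_common_genes: int = 10
    n_pathway_private_genes: int = 8
    n_offtarget_genes: int = 6
    n_general_link_genes: int = 24

    # chemical-protein links
    n_planted_compounds: int = 90
    links_per_planted: Tuple[int, int] = (1, 5)
    n_background_compounds: int = 210
    links_per_background: Tuple[int, int] = (1, 4)
    background_conf: Tuple[float, float] = (0.15, 0.89)
    planted_conf: Tuple[float, float] = (0.90, 1.0)

    # herbs
    n_herbs: int = 120
    ingredients_per_herb: Tuple[int, int] = (2, 12)
    category_weights: Tuple[int, ...] = (21, 123, 98, 64, 28, 21, 45, 18)
    n_excluded_unconventional: int = 2
    n_excluded_toxic: int = 2

    # synthetic lethality
    n_aml_pairs_high: int = 2
    n_aml_pairs_low: int = 3
    n_other_sl: int = 150
    n_offtarget_covered: int = 10
    n_covering_herbs: int = 5
    n_partner_herbs: int = 6
    sl_high_conf: Tuple[float, float] = (0.75, 0.95)
    sl_low_conf: Tuple[float, float] = (0.30, 0.70)

    # pathways
    n_shared_pathways: int = 35
    unique_pathways_per_group: Tuple[int, ...] = (20, 30, 25, 0, 15, 20, 0, 10)
    n_multi_pathways: int = 53
    n_decoy_pathways: int = 20
    n_decoy_genes: int = 600
    multi_core_per_group: int = 6

    def validate(self) -> None:
        """Raise :class:`ConfigError` on any inconsistency, before
        anything is generated or written."""
        def positive(name, value, floor=0):
            if value < floor:
                raise ConfigError(f"{name} must be >= {floor}, got {value}")

        for name in (
            "n_deg_up", "n_deg_down", "n_key", "n_unmatched", "n_planted_hubs",
            "n_hub_up", "n_keys_in_hubs", "n_partners", "n_herbs",
            "n_planted_compounds", "n_background_compounds", "n_other_sl",
        ):
            positive(name, getattr(self, name))
        positive("hub_threshold", self.hub_threshold, 1)
        positive("pa_m", self.pa_m, 1)
        n_deg = self.n_deg_up + self.n_deg_down
        if self.n_planted_hubs + self.n_unmatched > n_deg:
            raise ConfigError("planted hubs + unmatched DEGs exceed the DEG count")
        if self.n_hub_up > min(self.n_planted_hubs, self.n_deg_up):
            raise ConfigError("n_hub_up exceeds planted hubs or up-regulated DEGs")
        if self.n_planted_hubs - self.n_hub_up > self.n_deg_down:
            raise ConfigError("down-regulated hub count exceeds down DEGs")
        if self.n_keys_in_hubs > min(self.n_key, self.n_planted_hubs):
            raise ConfigError("n_keys_in_hubs exceeds n_key or planted hubs")
        n_sub_keys = self.n_key - self.n_keys_in_hubs
        n_matched_sub = n_deg - self.n_planted_hubs - self.n_unmatched
        if n_sub_keys > n_matched_sub:
            raise ConfigError("sub-threshold keys exceed matched sub-threshold DEGs")
        if self.n_flagship_up > self.n_hub_up:
            raise ConfigError("flagship up-targets exceed up-regulated hubs")
        if self.n_flagship_down > self.n_planted_hubs - self.n_hub_up:
            raise ConfigError("flagship down-targets exceed down-regulated hubs")
        n_sl_genes = 2 * (self.n_aml_pairs_high + self.n_aml_pairs_low)
        reserved = (
            self.n_flagship_up + self.n_flagship_down
            + self.n_pathway_common_genes + 8 * self.n_pathway_private_genes
            + n_sl_genes + self.n_offtarget_genes + self.n_general_link_genes
        )
        if reserved > self.n_planted_hubs:
            raise ConfigError(
                f"hub-gene allocation ({reserved}) exceeds planted hubs "
                f"({self.n_planted_hubs})"
            )
        if self.hub_degree_max < self.hub_threshold:
            raise ConfigError("hub_degree_max below hub_threshold")
        if self.n_partners < self.hub_degree_max:
            raise ConfigError("not enough partner proteins for the planted hub degrees")
        if len(self.category_weights) != 8 or any(w < 0 for w in self.category_weights):
            raise ConfigError("category_weights must be 8 non-negative numbers")
        if len(self.unique_pathways_per_group) != 8:
            raise ConfigError("unique_pathways_per_group must list 8 counts")
        n_special = (
            8 + self.n_covering_herbs + self.n_partner_herbs + 1
            + self.n_excluded_unconventional + self.n_excluded_toxic
        )
        if n_special > self.n_herbs:
            raise ConfigError("n_herbs too small for the planted herb roles")
        if self.n_covering_herbs < 2:
            raise ConfigError("need at least 2 covering herbs")
        if self.n_offtarget_covered > self.n_offtarget_genes * (self.n_offtarget_genes - 1) // 2:
            raise ConfigError("n_offtarget_covered exceeds pairs formable from off-target genes")


@dataclass
class SyntheticBundle:
    """Generated tables plus the ground-truth manifest."""

    config: GeneratorConfig
    deg_records: List[GeneRecord]
    network: InteractionNetwork
    links: List[ChemicalProteinLink]
    herbs: List[HerbRecord]
    sl_pairs: List[SLPairRecord]
    pathways: List[PathwayAnnotation]
    drug_targets: Dict[str, FrozenSet[str]]
    manifest: Dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_deg_table(self.deg_records, outdir / "degs.tsv")
        hio.write_ppi_edges(self.network, outdir / "ppi.tsv")
        hio.write_chemical_links(self.links, outdir / "chem_links.tsv")
        hio.write_herb_table(self.herbs, outdir / "herbs.tsv", outdir / "herb_ingredients.tsv")
        hio.write_sl_table(self.sl_pairs, outdir / "sl_pairs.tsv")
        hio.write_pathway_table(self.pathways, outdir / "pathways.tsv")
        import pandas as pd

        pd.DataFrame(
            {
                "drug_id": [f"D{i + 1:03d}" for i in range(len(self.drug_targets))],
                "drug_name": sorted(self.drug_targets),
                "targets": [";".join(sorted(self.drug_targets[d])) for d in sorted(self.drug_targets)],
            }
        ).to_csv(outdir / "drug_targets.tsv", sep="\t", index=False)
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")


def _sample_conf(rng, bounds: Tuple[float, float], size=None):
    lo, hi = bounds
    return rng.uniform(lo, hi, size=size)


def generate(config: GeneratorConfig) -> SyntheticBundle:
    """Generate the six-table bundle; reproducible given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ------------------------------------------------------------------ genes
    up_genes = [f"UP{i + 1:04d}" for i in range(config.n_deg_up)]
    down_genes = [f"DN{i + 1:04d}" for i in range(config.n_deg_down)]
    partners = [f"PP{i + 1:05d}" for i in range(config.n_partners)]
    decoy_genes = [f"DC{i + 1:04d}" for i in range(config.n_decoy_genes)]

    hub_up = up_genes[: config.n_hub_up]
    hub_down = down_genes[: config.n_planted_hubs - config.n_hub_up]
    hub_genes = hub_up + hub_down
    non_hub = up_genes[config.n_hub_up:] + down_genes[len(hub_down):]
    order = rng.permutation(len(non_hub))
    non_hub = [non_hub[i] for i in order]
    n_matched_sub = len(non_hub) - config.n_unmatched
    matched_sub = non_hub[:n_matched_sub]
    unmatched = non_hub[n_matched_sub:]

    keys = set(hub_genes[: config.n_keys_in_hubs])
    keys |= set(matched_sub[: config.n_key - config.n_keys_in_hubs])

    regulation = {g: "up" for g in up_genes}
    regulation.update({g: "down" for g in down_genes})
    deg_records = [
        GeneRecord(symbol=g, regulation=regulation[g], is_key=g in keys)
        for g in up_genes + down_genes
    ]

    # ------------------------------------------------- hub-gene allocation
    flagship_targets = hub_up[: config.n_flagship_up] + hub_down[: config.n_flagship_down]
    remaining = [g for g in hub_genes if g not in set(flagship_targets)]
    remaining = [remaining[i] for i in rng.permutation(len(remaining))]

    # slice sequentially from the shuffled remainder
    idx = 0

    def grab(n: int) -> List[str]:
        nonlocal idx
        out = remaining[idx : idx + n]
        idx += n
        return out

    common_genes = grab(config.n_pathway_common_genes)
    private_genes = {c: grab(config.n_pathway_private_genes) for c in range(1, 9)}
    n_high, n_low = config.n_aml_pairs_high, config.n_aml_pairs_low
    sl_high_genes = grab(2 * n_high)
    sl_low_genes = grab(2 * n_low)
    offtarget_genes = grab(config.n_offtarget_genes)
    general_genes = grab(config.n_general_link_genes)

    # ---------------------------------------------------------------- network
    bg_seed = int(rng.integers(0, 2**31 - 1))
    bg = nx.barabasi_albert_graph(config.n_partners, config.pa_m, seed=bg_seed)
    edges = [(partners[a], partners[b]) for a, b in bg.edges()]
    for gene in hub_genes:
        deg = int(rng.integers(config.hub_threshold, config.hub_degree_max + 1))
        chosen = rng.choice(config.n_partners, size=deg, replace=False)
        edges.extend((gene, partners[j]) for j in chosen)
    for gene in matched_sub:
        deg = int(rng.integers(1, config.hub_threshold))
        chosen = rng.choice(config.n_partners, size=deg, replace=False)
        edges.extend((gene, partners[j]) for j in chosen)
    network = InteractionNetwork(edges)

    # ------------------------------------------------------------- compounds
    links: List[ChemicalProteinLink] = []

    def add_links(compound: str, targets: Sequence[str], conf_bounds) -> None:
        confs = _sample_conf(rng, conf_bounds, size=len(targets))
        for t, c in zip(targets, confs):
            links.append(
                ChemicalProteinLink(
                    compound_id=compound, compound_name=compound, protein=t,
                    confidence=float(round(c, 6)),
                )
            )

    flagship_compounds = [f"flag{i + 1:02d}" for i in range(config.n_flagship_compounds)]
    split = np.array_split(np.arange(len(flagship_targets)), config.n_flagship_compounds)
    for comp, piece in zip(flagship_compounds, split):
        add_links(comp, [flagship_targets[j] for j in piece], config.planted_conf)

    add_links("uc1", common_genes, config.planted_conf)
    for c in range(1, 9):
        add_links(f"pc{c}", private_genes[c], config.planted_conf)

    high_pairs = [
        (sl_high_genes[2 * i], sl_high_genes[2 * i + 1]) for i in range(n_high)
    ]
    low_pairs = [(sl_low_genes[2 * i], sl_low_genes[2 * i + 1]) for i in range(n_low)]
    add_links("slcov1", list(high_pairs[0]), config.planted_conf)
    if n_high > 1:
        add_links("slcov2", list(high_pairs[1]), config.planted_conf)
    add_links("sla", [high_pairs[0][0]], config.planted_conf)
    if low_pairs:
        add_links("sllow", list(low_pairs[0]), config.planted_conf)
    add_links("sloff", offtarget_genes, config.planted_conf)

    planted_compounds = [f"plc{i + 1:04d}" for i in range(config.n_planted_compounds)]
    lo, hi = config.links_per_planted
    for comp in planted_compounds:
        n = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(general_genes), size=min(n, len(general_genes)), replace=False)
        add_links(comp, [general_genes[j] for j in chosen], config.planted_conf)

    background_compounds = [f"cmp{i + 1:04d}" for i in range(config.n_background_compounds)]
    all_background_targets = partners + up_genes + down_genes
    lo, hi = config.links_per_background
    for comp in background_compounds:
        n = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(all_background_targets), size=n, replace=False)
        add_links(comp, [all_background_targets[j] for j in chosen], config.background_conf)

    # ------------------------------------------------------------------ herbs
    herb_ids = [f"H{i + 1:03d}" for i in range(config.n_herbs)]
    weights = np.asarray(config.category_weights, dtype=float)
    weights = weights / weights.sum()
    categories = {hid: int(rng.choice(8, p=weights)) + 1 for hid in herb_ids}
    for c in range(1, 9):  # designated pathway herbs, one per category
        categories[herb_ids[c - 1]] = c

    i0 = 8
    covering = herb_ids[i0 : i0 + config.n_covering_herbs]
    i0 += config.n_covering_herbs
    partners_h = herb_ids[i0 : i0 + config.n_partner_herbs]
    i0 += config.n_partner_herbs
    flagship_herb = herb_ids[i0]
    i0 += 1
    excl_unconv = herb_ids[i0 : i0 + config.n_excluded_unconventional]
    i0 += config.n_excluded_unconventional
    excl_toxic = herb_ids[i0 : i0 + config.n_excluded_toxic]

    # covering herbs mimic the reported composition: tonic + heat-clearing
    for j, hid in enumerate(covering):
        categories[hid] = 3 if j < 2 else 2
    categories[flagship_herb] = 3

    general_compounds = planted_compounds + background_compounds
    mid = config.n_covering_herbs // 2
    group1 = covering[: mid + 1]
    group2 = covering[mid:]

    ing_lo, ing_hi = config.ingredients_per_herb

    def random_ingredients(n_lo: int, n_hi: int) -> set:
        n = int(rng.integers(n_lo, n_hi + 1))
        chosen = rng.choice(len(general_compounds), size=n, replace=False)
        return {general_compounds[j] for j in chosen}

    ingredients: Dict[str, set] = {}
    for hid in herb_ids:
        ingredients[hid] = random_ingredients(ing_lo, ing_hi)
    for c in range(1, 9):
        ingredients[herb_ids[c - 1]] = {"uc1", f"pc{c}"} | random_ingredients(1, 4)
    for hid in group1:
        ingredients[hid].add("slcov1")
    if n_high > 1:
        for hid in group2:
            ingredients[hid].add("slcov2")
    for hid in partners_h:
        ingredients[hid].add("sla")
    if low_pairs:
        ingredients[partners_h[0]].add("sllow")
    ingredients[covering[0]].add("sloff")
    ingredients[flagship_herb] = set(flagship_compounds)  # exact 83-target profile

    herbs = []
    for hid in herb_ids:
        excluded = hid in excl_unconv or hid in excl_toxic
        reason = None
        if hid in excl_unconv:
            reason = "unconventional"
        elif hid in excl_toxic:
            reason = "toxic"
        herbs.append(
            HerbRecord(
                herb_id=hid,
                latin_name=f"Herba ficta {hid[1:]}",
                pinyin_name=f"Syn Cao {hid[1:]}",
                category=categories[hid],
                ingredients=frozenset(ingredients[hid]),
                excluded=excluded,
                exclusion_reason=reason,
            )
        )

    # ------------------------------------------------------------------- SL
    sl_pairs: List[SLPairRecord] = []
    for a, b in high_pairs:
        conf = float(round(_sample_conf(rng, config.sl_high_conf), 6))
        sl_pairs.append(SLPairRecord(a, b, conf, frozenset({"AML"})))
    for a, b in low_pairs:
        conf = float(round(_sample_conf(rng, config.sl_low_conf), 6))
        sl_pairs.append(SLPairRecord(a, b, conf, frozenset({"AML"})))
    off_pairs = list(combinations(offtarget_genes, 2))[: config.n_offtarget_covered]
    for a, b in off_pairs:
        conf = float(round(rng.uniform(0.0, 1.0), 6))
        tag = _NON_AML_TAGS[int(rng.integers(0, len(_NON_AML_TAGS)))]
        sl_pairs.append(SLPairRecord(a, b, conf, frozenset({tag})))
    seen = {p.key for p in sl_pairs}
    n_random = config.n_other_sl - len(off_pairs)
    while n_random > 0:
        a, b = rng.choice(config.n_partners, size=2, replace=False)
        pa, pb = partners[int(a)], partners[int(b)]
        key = tuple(sorted((pa, pb)))
        if key in seen:
            continue
        seen.add(key)
        conf = float(round(rng.uniform(0.0, 1.0), 6))
        tag = _NON_AML_TAGS[int(rng.integers(0, len(_NON_AML_TAGS)))]
        sl_pairs.append(SLPairRecord(pa, pb, conf, frozenset({tag})))
        n_random -= 1

    # --------------------------------------------------------------- pathways
    pathways: List[PathwayAnnotation] = []
    profiles: Dict[int, set] = {c: set() for c in range(1, 9)}

    def decoys(n: int) -> List[str]:
        chosen = rng.choice(config.n_decoy_genes, size=n, replace=False)
        return [decoy_genes[j] for j in chosen]

    for i in range(config.n_shared_pathways):
        pid = f"PW_SH_{i + 1:03d}"
        n_core = int(rng.integers(6, len(common_genes) + 1))
        chosen = rng.choice(len(common_genes), size=n_core, replace=False)
        members = {common_genes[j] for j in chosen} | set(decoys(int(rng.integers(2, 6))))
        pathways.append(PathwayAnnotation(pid, f"Shared pathway {i + 1}", frozenset(members)))
        for c in range(1, 9):
            profiles[c].add(pid)
    for c in range(1, 9):
        for i in range(config.unique_pathways_per_group[c - 1]):
            pid = f"PW_UQ_{c}_{i + 1:02d}"
            n_core = int(rng.integers(5, config.n_pathway_private_genes + 1))
            chosen = rng.choice(config.n_pathway_private_genes, size=n_core, replace=False)
            members = {private_genes[c][j] for j in chosen} | set(decoys(int(rng.integers(2, 6))))
            pathways.append(
                PathwayAnnotation(pid, f"Group {c} unique pathway {i + 1}", frozenset(members))
            )
            profiles[c].add(pid)
    for i in range(config.n_multi_pathways):
        pid = f"PW_MU_{i + 1:03d}"
        size = int(rng.integers(2, 8))
        cats = sorted(int(c) + 1 for c in rng.choice(8, size=size, replace=False))
        members = set(decoys(int(rng.integers(2, 6))))
        core = min(config.multi_core_per_group, config.n_pathway_private_genes)
        for c in cats:
            chosen = rng.choice(config.n_pathway_private_genes, size=core, replace=False)
            members |= {private_genes[c][j] for j in chosen}
            profiles[c].add(pid)
        pathways.append(
            PathwayAnnotation(pid, f"Multi-group pathway {i + 1}", frozenset(members))
        )
    for i in range(config.n_decoy_pathways):
        pid = f"PW_DC_{i + 1:03d}"
        pathways.append(
            PathwayAnnotation(
                pid, f"Decoy pathway {i + 1}", frozenset(decoys(int(rng.integers(8, 16))))
            )
        )

    # ------------------------------------------------------------------ drugs
    drug_targets = {
        "Synthagen alfa": frozenset(flagship_targets[:2]),
        "Synthagen beta": frozenset(partners[:3]),
        "Synthagen gamma": frozenset(partners[3:5]),
        "Synthagen delta": frozenset({partners[5]}),
        "Synthagen epsilon": frozenset(partners[6:9]),
    }

    # --------------------------------------------------------------- manifest
    expected_pairs = sorted(
        {tuple(sorted(p)) for p in combinations(group1, 2)}
        | ({tuple(sorted(p)) for p in combinations(group2, 2)} if n_high > 1 else set())
        | {tuple(sorted((p, c))) for p in partners_h for c in group1}
    )
    union_pathways = set().union(*profiles.values())
    shared_pathways = set.intersection(*profiles.values())
    manifest = {
        "planted_hub_genes": sorted(hub_genes),
        "key_genes": sorted(keys),
        "n_sub_threshold_keys": config.n_key - config.n_keys_in_hubs,
        "expected_hub_count": len(set(hub_genes) | keys),
        "unmatched_genes": sorted(unmatched),
        "flagship_herb": flagship_herb,
        "flagship_targets": sorted(flagship_targets),
        "flagship_n_up": config.n_flagship_up,
        "flagship_n_down": config.n_flagship_down,
        "covering_herbs": sorted(set(group1) | (set(group2) if n_high > 1 else set())),
        "partner_herbs": sorted(partners_h),
        "expected_herb_pairs": [list(p) for p in expected_pairs],
        "aml_pairs_high": [
            {"genes": sorted(p.genes), "confidence": p.confidence}
            for p in sl_pairs[:n_high]
        ],
        "offtarget_counts": {covering[0]: len(off_pairs)},
        "excluded_herbs": sorted(excl_unconv + excl_toxic),
        "pathway_profiles": {str(c): sorted(s) for c, s in profiles.items()},
        "shared_pathways": sorted(shared_pathways),
        "n_union_pathways": len(union_pathways),
        "unique_pathway_counts": {
            str(c): config.unique_pathways_per_group[c - 1] for c in range(1, 9)
        },
        "drug_overlap": {"Synthagen alfa": sorted(flagship_targets[:2])},
        "seed": config.seed,
    }

    return SyntheticBundle(
        config=config,
        deg_records=deg_records,
        network=network,
        links=links,
        herbs=herbs,
        sl_pairs=sl_pairs,
        pathways=pathways,
        drug_targets=drug_targets,
        manifest=manifest,
    )
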