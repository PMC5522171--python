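"""Readers and writers for the pipeline's tab-separated table dialects.

All tables are UTF-8, tab-separated, with exactly one header row; lines
starting with ``#`` are comments. Gene symbols are normalized on read, so
all cross-table joins operate on one namespace. Each reader resolves
duplicates with a documented, inclusion-conservative rule and raises
:class:`~herbnet.types.TableParseError` (naming the line) on malformed
rows.

Schemas (column names exact)::

    degs.tsv              symbol  regulation  is_key
    ppi.tsv               protein_a  protein_b
    chem_links.tsv        compound_id  compound_name  protein  confidence
    herbs.tsv             herb_id  latin_name  pinyin_name  category  excluded  exclusion_reason
    herb_ingredients.tsv  herb_id  compound_id
    sl_pairs.tsv          gene_a  gene_b  confidence  diseases   (';'-separated tags)
    pathways.tsv          pathway_id  name  members               (';'-separated symbols)
    drug_targets.tsv      drug_id  drug_name  targets             (';'-separated symbols)
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import pandas as pd

from .types import (
    ChemicalProteinLink,
    GeneRecord,
    HerbRecord,
    InteractionNetwork,
    MalformedRecordError,
    PathwayAnnotation,
    SLPairRecord,
    TableParseError,
    normalize_symbol,
)

logger = logging.getLogger(__name__)

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


def _read_table(path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas-internal failures
        raise TableParseError(str(exc), path=str(path))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableParseError(
            f"missing column(s) {missing}; found {list(df.columns)}", path=str(path), line=1
        )
    unknown = [c for c in df.columns if c not in columns]
    if unknown:
        raise TableParseError(f"unknown column(s) {unknown}", path=str(path), line=1)
    return df


def _line_of(df_index: int) -> int:
    # header is line 1; data starts at line 2 (comment lines shift this, but
    # pandas hides them — the reported number is the data-row ordinal).
    return int(df_index) + 2


def _parse_bool(raw: str, path: str, line: int, column: str) -> bool:
    val = str(raw).strip().lower()
    if val in _TRUE:
        return True
    if val in _FALSE:
        return False
    raise TableParseError(f"column {column!r}: not a boolean: {raw!r}", path=path, line=line)


def read_deg_table(path) -> List[GeneRecord]:
    """Read a DEG table; duplicate symbols with conflicting annotation raise."""
    df = _read_table(path, ["symbol", "regulation", "is_key"])
    records: Dict[str, GeneRecord] = {}
    for idx, row in df.iterrows():
        line = _line_of(idx)
        try:
            rec = GeneRecord(
                symbol=row["symbol"],
                regulation=row["regulation"],
                is_key=_parse_bool(row["is_key"], str(path), line, "is_key"),
            )
        except MalformedRecordError as exc:
            raise TableParseError(str(exc), path=str(path), line=line)
        prev = records.get(rec.symbol)
        if prev is not None and prev != rec:
            raise TableParseError(
                f"conflicting duplicate records for {rec.symbol}", path=str(path), line=line
            )
        records[rec.symbol] = rec
    out = list(records.values())
    logger.info("read %d DEG records from %s", len(out), path)
    return out


def write_deg_table(records: Sequence[GeneRecord], path) -> None:
    df = pd.DataFrame(
        {
            "symbol": [r.symbol for r in records],
            "regulation": [r.regulation for r in records],
            "is_key": [str(r.is_key).lower() for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ppi_edges(path, min_conf: float = 0.0) -> InteractionNetwork:
    """Read an undirected edge list; unordered duplicates and self-loops collapse.

    An optional ``confidence`` column is accepted; edges below ``min_conf``
    are dropped (default 0.0 — no edge-confidence filtering).
    """
    path = Path(path)
    probe = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False, nrows=0)
    columns = ["protein_a", "protein_b"]
    if "confidence" in probe.columns:
        columns.append("confidence")
    df = _read_table(path, columns)
    edges = []
    for idx, row in df.iterrows():
        line = _line_of(idx)
        if "confidence" in columns:
            try:
                conf = float(row["confidence"])
            except ValueError:
                raise TableParseError(
                    f"confidence is not numeric: {row['confidence']!r}",
                    path=str(path), line=line,
                )
            if conf < min_conf:
                continue
        try:
            edges.append((row["protein_a"], row["protein_b"]))
        except MalformedRecordError as exc:  # pragma: no cover
            raise TableParseError(str(exc), path=str(path), line=line)
    try:
        net = InteractionNetwork(edges)
    except MalformedRecordError as exc:
        raise TableParseError(str(exc), path=str(path))
    logger.info("read %d edges (%d nodes) from %s", len(net), len(net.nodes), path)
    return net


def write_ppi_edges(network: InteractionNetwork, path) -> None:
    rows = sorted(network.edges)
    pd.DataFrame(rows, columns=["protein_a", "protein_b"]).to_csv(path, sep="\t", index=False)


def read_chemical_links(path, scale_1000: bool = False) -> List[ChemicalProteinLink]:
    """Read compound→protein links.

    ``scale_1000`` divides raw scores by 1000 (STITCH distributes 0–1000
    integer scores; thresholds in this package live on the unit scale).
    Duplicate (compound, protein) rows keep the maximum confidence —
    conservative toward inclusion at a ≥-threshold.
    """
    df = _read_table(path, ["compound_id", "compound_name", "protein", "confidence"])
    best: Dict[Tuple[str, str], ChemicalProteinLink] = {}
    for idx, row in df.iterrows():
        line = _line_of(idx)
        try:
            conf = float(row["confidence"])
        except ValueError:
            raise TableParseError(
                f"confidence is not numeric: {row['confidence']!r}", path=str(path), line=line
            )
        if scale_1000:
            conf = conf / 1000.0
        try:
            link = ChemicalProteinLink(
                compound_id=row["compound_id"],
                compound_name=row["compound_name"],
                protein=row["protein"],
                confidence=conf,
            )
        except MalformedRecordError as exc:
            raise TableParseError(str(exc), path=str(path), line=line)
        key = (link.compound_id, link.protein)
        prev = best.get(key)
        if prev is None or link.confidence > prev.confidence:
            best[key] = link
    out = list(best.values())
    logger.info("read %d chemical-protein links from %s", len(out), path)
    return out


def write_chemical_links(links: Sequence[ChemicalProteinLink], path) -> None:
    rows = sorted(links, key=lambda l: (l.compound_id, l.protein))
    pd.DataFrame(
        {
            "compound_id": [l.compound_id for l in rows],
            "compound_name": [l.compound_name for l in rows],
            "protein": [l.protein for l in rows],
            "confidence": [repr(l.confidence) for l in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_herb_table(herbs_path, ingredients_path) -> List[HerbRecord]:
    """Read the herb annotation table and its herb→ingredient mapping."""
    hdf = _read_table(herbs_path, [
        "herb_id", "latin_name", "pinyin_name", "category", "excluded", "exclusion_reason",
    ])
    idf = _read_table(ingredients_path, ["herb_id", "compound_id"])
    ing: Dict[str, set] = {}
    for _, row in idf.iterrows():
        ing.setdefault(str(row["herb_id"]).strip(), set()).add(str(row["compound_id"]).strip())
    herbs: Dict[str, HerbRecord] = {}
    for idx, row in hdf.iterrows():
        line = _line_of(idx)
        hid = str(row["herb_id"]).strip()
        try:
            rec = HerbRecord(
                herb_id=hid,
                latin_name=str(row["latin_name"]).strip(),
                pinyin_name=str(row["pinyin_name"]).strip(),
                category=int(row["category"]),
                ingredients=frozenset(ing.get(hid, set())),
                excluded=_parse_bool(row["excluded"], str(herbs_path), line, "excluded"),
                exclusion_reason=row["exclusion_reason"] or None,
            )
        except (MalformedRecordError, ValueError) as exc:
            raise TableParseError(str(exc), path=str(herbs_path), line=line)
        if hid in herbs:
            raise TableParseError(f"duplicate herb_id {hid}", path=str(herbs_path), line=line)
        herbs[hid] = rec
    orphans = set(ing) - set(herbs)
    if orphans:
        logger.warning("%d ingredient rows reference unknown herb_ids: %s",
                       len(orphans), sorted(orphans)[:5])
    logger.info("read %d herbs from %s", len(herbs), herbs_path)
    return list(herbs.values())


def write_herb_table(herbs: Sequence[HerbRecord], herbs_path, ingredients_path) -> None:
    rows = sorted(herbs, key=lambda h: h.herb_id)
    pd.DataFrame(
        {
            "herb_id": [h.herb_id for h in rows],
            "latin_name": [h.latin_name for h in rows],
            "pinyin_name": [h.pinyin_name for h in rows],
            "category": [h.category for h in rows],
            "excluded": [str(h.excluded).lower() for h in rows],
            "exclusion_reason": [h.exclusion_reason or "" for h in rows],
        }
    ).to_csv(herbs_path, sep="\t", index=False)
    ing_rows = [(h.herb_id, c) for h in rows for c in sorted(h.ingredients)]
    pd.DataFrame(ing_rows, columns=["herb_id", "compound_id"]).to_csv(
        ingredients_path, sep="\t", index=False
    )


def read_sl_table(path) -> List[SLPairRecord]:
    """Read SL gene pairs; duplicates keep max confidence ∪ disease tags."""
    df = _read_table(path, ["gene_a", "gene_b", "confidence", "diseases"])
    best: Dict[Tuple[str, str], SLPairRecord] = {}
    for idx, row in df.iterrows():
        line = _line_of(idx)
        try:
            rec = SLPairRecord(
                gene_a=row["gene_a"],
                gene_b=row["gene_b"],
                confidence=float(row["confidence"]),
                diseases=frozenset(t for t in str(row["diseases"]).split(";") if t.strip()),
            )
        except (MalformedRecordError, ValueError) as exc:
            raise TableParseError(str(exc), path=str(path), line=line)
        prev = best.get(rec.key)
        if prev is not None:
            rec = SLPairRecord(
                gene_a=rec.gene_a,
                gene_b=rec.gene_b,
                confidence=max(rec.confidence, prev.confidence),
                diseases=rec.diseases | prev.diseases,
            )
        best[rec.key] = rec
    out = list(best.values())
    logger.info("read %d SL pairs from %s", len(out), path)
    return out


def write_sl_table(pairs: Sequence[SLPairRecord], path) -> None:
    rows = sorted(pairs, key=lambda p: p.key)
    pd.DataFrame(
        {
            "gene_a": [p.gene_a for p in rows],
            "gene_b": [p.gene_b for p in rows],
            "confidence": [repr(p.confidence) for p in rows],
            "diseases": [";".join(sorted(p.diseases)) for p in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_pathway_table(path) -> List[PathwayAnnotation]:
    df = _read_table(path, ["pathway_id", "name", "members"])
    out: Dict[str, PathwayAnnotation] = {}
    for idx, row in df.iterrows():
        line = _line_of(idx)
        try:
            rec = PathwayAnnotation(
                pathway_id=row["pathway_id"],
                name=str(row["name"]).strip(),
                members=frozenset(m for m in str(row["members"]).split(";") if m.strip()),
            )
        except MalformedRecordError as exc:
            raise TableParseError(str(exc), path=str(path), line=line)
        if rec.pathway_id in out:
            raise TableParseError(
                f"duplicate pathway_id {rec.pathway_id}", path=str(path), line=line
            )
        out[rec.pathway_id] = rec
    logger.info("read %d pathways from %s", len(out), path)
    return list(out.values())


def write_pathway_table(pathways: Sequence[PathwayAnnotation], path) -> None:
    rows = sorted(pathways, key=lambda p: p.pathway_id)
    pd.DataFrame(
        {
            "pathway_id": [p.pathway_id for p in rows],
            "name": [p.name for p in rows],
            "members": [";".join(sorted(p.members)) for p in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_gmt(path) -> List[PathwayAnnotation]:
    """Read gene sets in GMT format (id TAB description TAB gene TAB gene...)."""
    out: List[PathwayAnnotation] = []
    seen = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw.strip() or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 3:
                raise TableParseError(
                    "GMT lines need id, description and >=1 gene", path=str(path), line=lineno
                )
            pid, name, genes = parts[0], parts[1], [g for g in parts[2:] if g.strip()]
            if pid in seen:
                raise TableParseError(f"duplicate gene-set id {pid}", path=str(path), line=lineno)
            seen.add(pid)
            try:
                out.append(PathwayAnnotation(pathway_id=pid, name=name, members=frozenset(genes)))
            except MalformedRecordError as exc:
                raise TableParseError(str(exc), path=str(path), line=lineno)
    return out


def read_drug_targets(path) -> Dict[str, frozenset]:
    """Read an approved-drug target table into {drug_name: target gene set}."""
    df = _read_table(path, ["drug_id", "drug_name", "targets"])
    out: Dict[str, frozenset] = {}
    for idx, row in df.iterrows():
        line = _line_of(idx)
        name = str(row["drug_name"]).strip()
        try:
            targets = frozenset(
                normalize_symbol(t) for t in str(row["targets"]).split(";") if t.strip()
            )
        except MalformedRecordError as exc:
            raise TableParseError(str(exc), path=str(path), line=line)
        out[name] = out.get(name, frozenset()) | targets
    return out


def read_feature_rules(path) -> Dict[str, List[str]]:
    """Read the clinical-feature→candidate-herb rule table.

    Schema: ``feature_tag`` TAB ``herb_ids`` (';'-separated, order kept).
    Tags are normalized lower-case.
    """
    df = _read_table(path, ["feature_tag", "herb_ids"])
    rules: Dict[str, List[str]] = {}
    for _, row in df.iterrows():
        tag = str(row["feature_tag"]).strip().lower()
        herbs = [h.strip() for h in str(row["herb_ids"]).split(";") if h.strip()]
        rules.setdefault(tag, []).extend(h for h in herbs if h not in rules.get(tag, []))
    return rules
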