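"""Readers and writers for every file format the pipeline touches.

Tabular files are CSV or TSV (delimiter chosen by extension: ``.tsv`` is
tab, everything else comma) with a mandatory header.  Gene sets use the
standard GMT layout.  All writers round-trip: writing an object and
reading it back reproduces the object.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .datamodel import (
    AdmetScores,
    CompoundRecord,
    DTIRecord,
    FingerprintTable,
    GeneSet,
    HerbFormula,
    PhyschemProfile,
    ValidationReport,
    normalize_gene,
)

log = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: documented compound-table columns (compound_id and name mandatory)
COMPOUND_COLUMNS = ["compound_id", "name", "smiles", "mw", "alogp", "hbd", "hba", "hia", "bbb"]


def _sep(path: PathLike) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def _read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)


def _num(value: str, column: str, row: int, kind=float) -> Optional[float]:
    """Parse one numeric cell; blank means absent, garbage is an error."""
    if value == "" or value.lower() in ("na", "nan", "none"):
        return None
    try:
        out = kind(float(value))
    except ValueError:
        raise ValueError(f"non-numeric {column}={value!r} at data row {row}") from None
    if kind is int and not float(value).is_integer():
        raise ValueError(f"non-integer {column}={value!r} at data row {row}")
    return out


def read_compound_table(path: PathLike) -> list[CompoundRecord]:
    df = _read_table(path)
    for col in ("compound_id", "name"):
        if col not in df.columns:
            raise ValueError(f"compound table missing required column {col!r}")
    records: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        cid = row["compound_id"].strip()
        if cid in seen:
            raise ValueError(f"duplicate compound_id {cid!r}")
        seen.add(cid)
        physchem_vals = {
            "mw": _num(row.get("mw", ""), "mw", i),
            "alogp": _num(row.get("alogp", ""), "alogp", i),
            "hbd": _num(row.get("hbd", ""), "hbd", i, int),
            "hba": _num(row.get("hba", ""), "hba", i, int),
        }
        physchem = (
            PhyschemProfile(**physchem_vals)
            if any(v is not None for v in physchem_vals.values())
            else None
        )
        hia = _num(row.get("hia", ""), "hia", i)
        bbb = _num(row.get("bbb", ""), "bbb", i)
        admet = AdmetScores(hia, bbb) if hia is not None and bbb is not None else None
        smiles = row.get("smiles", "").strip() or None
        records.append(CompoundRecord(cid, row["name"], smiles, physchem, admet))
    return records


def write_compound_table(records: Iterable[CompoundRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        p = r.physchem or PhyschemProfile()
        rows.append(
            {
                "compound_id": r.compound_id,
                "name": r.name,
                "smiles": r.smiles or "",
                "mw": "" if p.mw is None else p.mw,
                "alogp": "" if p.alogp is None else p.alogp,
                "hbd": "" if p.hbd is None else p.hbd,
                "hba": "" if p.hba is None else p.hba,
                "hia": "" if r.admet is None else r.admet.hia_prob,
                "bbb": "" if r.admet is None else r.admet.bbb_prob,
            }
        )
    pd.DataFrame(rows, columns=COMPOUND_COLUMNS).to_csv(path, sep=_sep(path), index=False)


def read_gene_sets_gmt(path: PathLike) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has {len(fields)} fields, need >= 3")
            gs = GeneSet(fields[0], fields[1], frozenset(fields[2:]))
            log.info("gene set %s: %d genes", gs.set_id, len(gs))
            sets.append(gs)
    return sets


def write_gene_sets_gmt(sets: Iterable[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.genes)]) + "\n")


def read_dti_table(path: PathLike) -> list[DTIRecord]:
    df = _read_table(path)
    for col in ("compound_id", "gene_symbol"):
        if col not in df.columns:
            raise ValueError(f"DTI table missing required column {col!r}")
    records: list[DTIRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = row._asdict()
        prov = row.get("provenance", "").strip() or "known"
        key = (row["compound_id"], normalize_gene(row["gene_symbol"]), prov)
        if key in seen:
            raise ValueError(f"duplicate DTI {key} at data row {i}")
        seen.add(key)
        records.append(
            DTIRecord(
                compound_id=row["compound_id"].strip(),
                target=row["gene_symbol"],
                provenance=prov,
                score=_num(row.get("score", ""), "score", i),
            )
        )
    return records


def write_dti_table(records: Iterable[DTIRecord], path: PathLike) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "gene_symbol": r.target,
            "provenance": r.provenance,
            "score": "" if r.score is None else repr(r.score),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["compound_id", "gene_symbol", "provenance", "score"]).to_csv(
        path, sep=_sep(path), index=False
    )


def read_fingerprint_table(path: PathLike) -> FingerprintTable:
    df = _read_table(path)
    id_col = df.columns[0]
    bit_names = list(df.columns[1:])
    try:
        bits = df[bit_names].astype(int).to_numpy()
    except ValueError as exc:
        raise ValueError(f"non-integer fingerprint value: {exc}") from None
    return FingerprintTable(list(df[id_col]), bit_names, bits)  # 0/1 check in ctor


def write_fingerprint_table(table: FingerprintTable, path: PathLike) -> None:
    df = pd.DataFrame(table.bits, columns=table.bit_names)
    df.insert(0, "compound_id", table.compound_ids)
    df.to_csv(path, sep=_sep(path), index=False)


def read_herb_table(path: PathLike) -> list[HerbFormula]:
    """Read the long-format herb membership table (one row per compound)."""
    df = _read_table(path)
    for col in ("herb_id", "compound_id"):
        if col not in df.columns:
            raise ValueError(f"herb table missing required column {col!r}")
    herbs: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        row = row._asdict()
        h = herbs.setdefault(
            row["herb_id"],
            {
                "name": row.get("name", row["herb_id"]) or row["herb_id"],
                "role_class": row.get("role_class", "").strip() or None,
                "compound_ids": set(),
            },
        )
        h["compound_ids"].add(row["compound_id"].strip())
    return [
        HerbFormula(hid, h["name"], frozenset(h["compound_ids"]), h["role_class"])
        for hid, h in herbs.items()
    ]


def write_herb_table(herbs: Iterable[HerbFormula], path: PathLike) -> None:
    rows = [
        {
            "herb_id": h.herb_id,
            "name": h.name,
            "role_class": h.role_class or "",
            "compound_id": cid,
        }
        for h in herbs
        for cid in sorted(h.compound_ids)
    ]
    pd.DataFrame(rows, columns=["herb_id", "name", "role_class", "compound_id"]).to_csv(
        path, sep=_sep(path), index=False
    )


def write_network_tsv(network, path: PathLike) -> None:
    """Write a DTINetwork as an edge-list TSV readable by read_dti_table."""
    write_dti_table(network.to_records(), path)


def read_network_tsv(path: PathLike):
    from .network import assemble_network

    records = read_dti_table(path)
    known = [r for r in records if r.provenance == "known"]
    predicted = [r for r in records if r.provenance == "predicted"]
    return assemble_network(known, predicted)


def validate_dataset(
    compounds: list[CompoundRecord],
    herbs: list[HerbFormula],
    fingerprints: Optional[FingerprintTable],
    dtis: list[DTIRecord],
    gene_sets: list[GeneSet],
) -> ValidationReport:
    """Cross-check all loaded components and report inconsistencies.

    Reporting only: orphan references and unusable compounds come back as
    warnings/notes, never exceptions, so a run can proceed on the usable
    subset with full visibility of what was dropped.
    """
    report = ValidationReport()
    compound_ids = {c.compound_id for c in compounds}

    for h in herbs:
        orphans = h.compound_ids - compound_ids
        if orphans:
            report.warnings.append(
                f"herb {h.herb_id} references unknown compounds: {sorted(orphans)[:5]}"
                + ("..." if len(orphans) > 5 else "")
            )

    dti_compounds = {r.compound_id for r in dtis}
    unknown_dti = dti_compounds - compound_ids
    if unknown_dti:
        report.warnings.append(
            f"{len(unknown_dti)} DTI compound(s) absent from compound table: "
            f"{sorted(unknown_dti)[:5]}" + ("..." if len(unknown_dti) > 5 else "")
        )

    if fingerprints is not None:
        missing_fp = compound_ids - set(fingerprints.compound_ids)
        if missing_fp:
            report.warnings.append(
                f"{len(missing_fp)} compound(s) lack fingerprints (unusable for diffusion)"
            )
        zero_rows = [
            cid
            for cid, row in zip(fingerprints.compound_ids, fingerprints.bits)
            if not row.any()
        ]
        for cid in zero_rows:
            report.warnings.append(f"compound {cid}: no substructures; excluded from diffusion")

    target_universe = {r.target for r in dtis}
    for gs in gene_sets:
        untargeted = gs.genes - target_universe
        if untargeted:
            report.info.append(
                f"gene set {gs.set_id}: {len(untargeted)}/{len(gs)} gene(s) not targeted "
                "by any compound"
            )
    return report
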