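"""Readers and writers for the package's on-disk formats.

* reference proteomes: plain FASTA, accession = first header token, optional
  ``taxon=`` and ``contaminant`` tags in the description;
* PSM tables: UTF-8 TSV, one PSM per line, with ``modifications`` encoded as
  a semicolon list ``pos:name:Δmass`` and ``substitutions`` as
  ``pos:db_aa>obs_aa`` (protein coordinates, 1-based);
* ortholog truth: TSV of (accession, position, target_aa, db_aa);
* simulation configs: a flat YAML file.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import PSMRecord
from .filters import PSM_COLUMNS
from .sim import IdentificationModel, OrthologTruth, ReferenceProteome, SimulationConfig


def write_proteome_fasta(proteome: ReferenceProteome, path) -> None:
    records = []
    for acc, seq in proteome.proteins.items():
        desc = f"taxon={proteome.taxon}"
        if acc in proteome.contaminants:
            desc += " contaminant"
        records.append(SeqRecord(Seq(seq), id=acc, description=desc))
    SeqIO.write(records, path, "fasta")


def read_proteome_fasta(path, taxon: Optional[str] = None) -> ReferenceProteome:
    proteins: Dict[str, str] = {}
    contaminants = set()
    seen_taxon = taxon
    for rec in SeqIO.parse(path, "fasta"):
        proteins[rec.id] = str(rec.seq)
        tokens = rec.description.split()
        if "contaminant" in tokens:
            contaminants.add(rec.id)
        for tok in tokens:
            if tok.startswith("taxon=") and seen_taxon is None:
                seen_taxon = tok[len("taxon="):]
    return ReferenceProteome(
        taxon=seen_taxon or "unknown",
        proteins=proteins,
        contaminants=frozenset(contaminants),
    )


def parse_substitutions(text: str) -> Tuple[Tuple[int, str, str], ...]:
    """Decode a ``pos:db_aa>obs_aa;...`` list (empty string -> no subs)."""
    if not text or pd.isna(text):
        return ()
    out = []
    for item in str(text).split(";"):
        pos, rest = item.split(":")
        db_aa, obs_aa = rest.split(">")
        out.append((int(pos), db_aa, obs_aa))
    return tuple(out)


def format_substitutions(subs) -> str:
    return ";".join(f"{p}:{d}>{o}" for p, d, o in subs)


def parse_modifications(text: str) -> Tuple[Tuple[int, str, float], ...]:
    """Decode a ``pos:name:delta_mass;...`` list (empty string -> none)."""
    if not text or pd.isna(text):
        return ()
    out = []
    for item in str(text).split(";"):
        pos, name, delta = item.split(":")
        out.append((int(pos), name, float(delta)))
    return tuple(out)


def format_modifications(mods) -> str:
    return ";".join(f"{p}:{n}:{m:.5f}" for p, n, m in mods)


def write_psm_table(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False, columns=[
        c for c in PSM_COLUMNS if c in psms.columns
    ] + [c for c in psms.columns if c not in PSM_COLUMNS])


def read_psm_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"dataset_id": str, "scan_id": str},
        keep_default_na=False,
    )
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} missing columns: {missing}")
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["score"] = df["score"].astype(float)
    return df


def psm_record_from_row(row) -> PSMRecord:
    """Build a :class:`PSMRecord` from one PSM-table row (Series or tuple)."""
    get = row.get if hasattr(row, "get") else lambda k: getattr(row, k)
    return PSMRecord(
        dataset_id=str(get("dataset_id")),
        scan_id=str(get("scan_id")),
        search_label=get("search_label"),
        peptide=get("peptide"),
        accession=get("accession"),
        start=int(get("start")),
        end=int(get("end")),
        score=float(get("score")),
        modifications=parse_modifications(get("modifications")),
        suggested_substitutions=parse_substitutions(get("substitutions")),
    )


def write_truth_tsv(truth: OrthologTruth, path) -> None:
    rows = [
        (acc, pos, t_aa, d_aa)
        for acc, subs in sorted(truth.substitutions.items())
        for pos, t_aa, d_aa in subs
    ]
    df = pd.DataFrame(rows, columns=["accession", "position", "target_aa", "db_aa"])
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path, target_label: str, db_label: str) -> OrthologTruth:
    df = pd.read_csv(path, sep="\t")
    subs: Dict[str, List[Tuple[int, str, str]]] = {}
    for r in df.itertuples():
        subs.setdefault(r.accession, []).append(
            (int(r.position), r.target_aa, r.db_aa)
        )
    return OrthologTruth(
        target_label=target_label, db_label=db_label, substitutions=subs
    )


def write_config_yaml(config: SimulationConfig, path) -> None:
    data = dataclasses.asdict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_config_yaml(path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    model = data.pop("id_model", None)
    if model is not None:
        for key in ("score_law_correct", "score_law_incorrect"):
            if key in model:
                model[key] = tuple(model[key])
        data["id_model"] = IdentificationModel(**model)
    for key in ("protein_length_range", "divergence_per_db", "db_labels"):
        if key in data:
            data[key] = tuple(data[key])
    config = SimulationConfig(**data)
    config.validate()
    return config
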