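"""Flat data model: drug table, directional pair table, label catalog.

Files are plain delimited text (comma or tab, auto-detected on read):

``drugs.csv``
    ``drug_id, smiles`` plus CYP role columns in one of two dialects:
    *split* — ``cyp_<enzyme>_victim`` in ``{substrate, none}`` and
    ``cyp_<enzyme>_perp`` in ``{inhibitor, inducer, none}`` (default
    writer dialect; expresses a drug that is both substrate and
    perpetrator of an enzyme); *role* — a single ``cyp_<enzyme>`` column
    in ``{substrate, inhibitor, inducer, none}``.
``pairs.csv``
    ``victim_id, perpetrator_id, label`` — ordered pairs, A affected by B.
``labels.csv``
    ``label, description`` — the 19-class catalog, descriptions holding
    DRUG_A / DRUG_B placeholders.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from sklearn.model_selection import train_test_split

from .cyp_features import CYP_PANEL, CYPProfile
from .errors import SchemaError, SplitError

logger = logging.getLogger(__name__)

N_CLASSES = 19

_VICTIM_ROLES = {"substrate", "none"}
_PERP_ROLES = {"inhibitor", "inducer", "none"}
_SINGLE_ROLES = {"substrate", "inhibitor", "inducer", "none"}


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str
    cyp_profile: CYPProfile

    def __post_init__(self):
        if not self.smiles:
            raise SchemaError(f"{self.drug_id}: empty SMILES")


@dataclass(frozen=True)
class DDIRecord:
    """Directional interaction: ``victim_id`` is affected by ``perpetrator_id``."""

    victim_id: str
    perpetrator_id: str
    label: int

    def __post_init__(self):
        if self.victim_id == self.perpetrator_id:
            raise SchemaError(f"self-pair {self.victim_id}")
        if not 1 <= int(self.label) <= N_CLASSES:
            raise SchemaError(f"label {self.label} outside 1..{N_CLASSES}")


@dataclass(frozen=True)
class LabelCatalog:
    entries: dict[int, str]

    def __post_init__(self):
        if set(self.entries) != set(range(1, N_CLASSES + 1)):
            raise SchemaError(f"catalog must map exactly 1..{N_CLASSES}")
        for k, text in self.entries.items():
            if "DRUG_A" not in text or "DRUG_B" not in text:
                raise SchemaError(f"label {k} description lacks DRUG_A/DRUG_B placeholders")

    @property
    def labels(self) -> list[int]:
        return sorted(self.entries)

    def describe(self, label: int, victim: str, perpetrator: str) -> str:
        return self.entries[label].replace("DRUG_A", victim).replace("DRUG_B", perpetrator)


def default_catalog() -> LabelCatalog:
    """Generic 19-entry catalog; replace descriptions with curated text as available."""
    entries = {}
    for e_idx, enzyme in enumerate(CYP_PANEL[:6]):
        entries[1 + e_idx] = (
            "The serum concentration of DRUG_A can be increased when combined "
            f"with DRUG_B (CYP{enzyme}-mediated inhibition of metabolism, type {1 + e_idx})."
        )
        entries[7 + e_idx] = (
            "The serum concentration of DRUG_A can be decreased when combined "
            f"with DRUG_B (CYP{enzyme}-mediated induction of metabolism, type {7 + e_idx})."
        )
    for i in range(13, 20):
        entries[i] = (
            "The risk or severity of adverse effects can be changed when DRUG_A "
            f"is combined with DRUG_B (physicochemical interaction type {i})."
        )
    return LabelCatalog(entries)


def _sniff_sep(path: Path) -> str:
    sample = Path(path).read_text(encoding="utf-8")[:4096]
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def _read_table(path, sep: str | None) -> pd.DataFrame:
    sep = sep or _sniff_sep(Path(path))
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def _profile_from_row(drug_id: str, row: pd.Series, dialect: str,
                      row_no: int, conflict_policy: str) -> CYPProfile:
    substrates, inhibitors, inducers = set(), set(), set()
    for enzyme in CYP_PANEL:
        if dialect == "split":
            v = row[f"cyp_{enzyme}_victim"].strip().lower()
            p = row[f"cyp_{enzyme}_perp"].strip().lower()
            if v not in _VICTIM_ROLES:
                raise SchemaError(
                    f"row {row_no}, column cyp_{enzyme}_victim: bad role token {v!r}")
            if p not in _PERP_ROLES:
                raise SchemaError(
                    f"row {row_no}, column cyp_{enzyme}_perp: bad role token {p!r}")
            if v == "substrate":
                substrates.add(enzyme)
            if p == "inhibitor":
                inhibitors.add(enzyme)
            elif p == "inducer":
                inducers.add(enzyme)
        else:
            r = row[f"cyp_{enzyme}"].strip().lower()
            if r not in _SINGLE_ROLES:
                raise SchemaError(
                    f"row {row_no}, column cyp_{enzyme}: bad role token {r!r}")
            if r == "substrate":
                substrates.add(enzyme)
            elif r == "inhibitor":
                inhibitors.add(enzyme)
            elif r == "inducer":
                inducers.add(enzyme)
    return CYPProfile(drug_id, frozenset(substrates), frozenset(inhibitors),
                      frozenset(inducers), conflict_policy=conflict_policy)


def read_drug_table(path, sep: str | None = None,
                    conflict_policy: str = "error") -> list[DrugRecord]:
    """Read and validate a drug table; the CYP dialect is detected from headers."""
    df = _read_table(path, sep)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    if all(f"cyp_{e}_victim" in df.columns and f"cyp_{e}_perp" in df.columns
           for e in CYP_PANEL):
        dialect = "split"
    elif all(f"cyp_{e}" in df.columns for e in CYP_PANEL):
        dialect = "role"
    else:
        raise SchemaError(
            f"missing CYP role columns in {path}: expected cyp_<enzyme> or "
            "cyp_<enzyme>_victim/cyp_<enzyme>_perp for all 12 enzymes")
    dup = df["drug_id"][df["drug_id"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicated drug_id(s): {sorted(set(dup))}")
    records = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):  # 1 header line
        profile = _profile_from_row(row["drug_id"], row, dialect, row_no, conflict_policy)
        records.append(DrugRecord(row["drug_id"], row["smiles"], profile))
    return records


def write_drug_table(drugs: list[DrugRecord], path, sep: str = ",") -> None:
    """Write a drug table in the split CYP dialect."""
    rows = []
    for d in drugs:
        row = {"drug_id": d.drug_id, "smiles": d.smiles}
        for e in CYP_PANEL:
            row[f"cyp_{e}_victim"] = "substrate" if e in d.cyp_profile.substrates else "none"
            if e in d.cyp_profile.inhibitors:
                row[f"cyp_{e}_perp"] = "inhibitor"
            elif e in d.cyp_profile.inducers:
                row[f"cyp_{e}_perp"] = "inducer"
            else:
                row[f"cyp_{e}_perp"] = "none"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def read_pair_table(path, sep: str | None = None,
                    drug_ids: set[str] | None = None) -> list[DDIRecord]:
    """Read the directional pair table; exact duplicate rows are dropped with a warning."""
    df = _read_table(path, sep)
    for col in ("victim_id", "perpetrator_id", "label"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    n0 = len(df)
    df = df.drop_duplicates()
    if len(df) < n0:
        logger.warning("dropped %d exact duplicate pair rows", n0 - len(df))
    records = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=2):
        try:
            label = int(row["label"])
        except ValueError:
            raise SchemaError(f"row {row_no}: non-integer label {row['label']!r}")
        rec = DDIRecord(row["victim_id"], row["perpetrator_id"], label)
        if drug_ids is not None:
            for did in (rec.victim_id, rec.perpetrator_id):
                if did not in drug_ids:
                    raise SchemaError(f"row {row_no}: unknown drug id {did!r}")
        records.append(rec)
    return records


def write_pair_table(pairs: list[DDIRecord], path, sep: str = ",") -> None:
    pd.DataFrame(
        [{"victim_id": p.victim_id, "perpetrator_id": p.perpetrator_id,
          "label": p.label} for p in pairs]
    ).to_csv(path, sep=sep, index=False)


def read_label_catalog(path, sep: str | None = None) -> LabelCatalog:
    df = _read_table(path, sep)
    for col in ("label", "description"):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r} in {path}")
    return LabelCatalog({int(r["label"]): r["description"] for _, r in df.iterrows()})


def write_label_catalog(catalog: LabelCatalog, path, sep: str = ",") -> None:
    pd.DataFrame(
        [{"label": k, "description": catalog.entries[k]} for k in catalog.labels]
    ).to_csv(path, sep=sep, index=False)


def filter_low_count_classes(pairs: list[DDIRecord], min_count: int) -> list[DDIRecord]:
    """Drop records of classes rarer than ``min_count``; original ids are kept."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[int, int] = {}
    for p in pairs:
        counts[p.label] = counts.get(p.label, 0) + 1
    removed = sorted(c for c, n in counts.items() if n < min_count)
    if removed:
        logger.info("low-count cutoff removed classes %s (min_count=%d)",
                    removed, min_count)
    kept = [p for p in pairs if counts[p.label] >= min_count]
    if not kept:
        logger.warning("low-count cutoff removed every record")
    return kept


def stratified_split(pairs: list[DDIRecord], train_fraction: float = 0.70,
                     seed: int = 0) -> tuple[list[DDIRecord], list[DDIRecord]]:
    """Class-stratified train/test partition, deterministic given the seed."""
    labels = [p.label for p in pairs]
    singletons = sorted({l for l in labels if labels.count(l) == 1})
    if singletons:
        raise SplitError(
            f"classes {singletons} have a single record; apply "
            "filter_low_count_classes before splitting")
    train, test = train_test_split(
        pairs, train_size=train_fraction, stratify=labels, random_state=seed)
    return list(train), list(test)
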