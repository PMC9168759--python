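"""Readers and writers for the four external formats.

The package consumes MAF-like tab-separated mutation records, a
gene x sample expression TSV, a clinical TSV and GMT gene-set files.
Only three MAF columns are consumed (gene symbol, sample barcode,
variant classification); every other column is ignored.  All writers
emit plain TSV so that a written table re-reads identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAF_REQUIRED_COLUMNS = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")

#: MAF controlled vocabulary for Variant_Classification.  Unknown labels are
#: retained in the table but logged, so exotic dialects do not lose records.
MAF_VOCABULARY = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation", "Silent",
    "Splice_Site", "Splice_Region", "Translation_Start_Site",
    "Frame_Shift_Del", "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins",
    "3'UTR", "5'UTR", "3'Flank", "5'Flank", "Intron", "IGR", "RNA",
    "Targeted_Region", "De_novo_Start_InFrame", "De_novo_Start_OutOfFrame",
})

#: Non-silent classes that count toward TMB and the binary mutation matrix:
#: nonsense, missense, splice site, stop-codon read-through, start-codon
#: change, frame-shift and in-frame indels.
NON_SILENT_CLASSES = frozenset({
    "Nonsense_Mutation", "Missense_Mutation", "Splice_Site", "Nonstop_Mutation",
    "Translation_Start_Site", "Frame_Shift_Del", "Frame_Shift_Ins",
    "In_Frame_Del", "In_Frame_Ins",
})

SEX_LABELS = ("male", "female")


class FormatError(ValueError):
    """A file violates its format contract (missing column, bad cell, ...)."""


@dataclass
class GeneSetCollection:
    """Named gene sets parsed from a GMT file.

    ``sets`` maps set name -> ordered unique member genes; ``descriptions``
    carries the second GMT field per set.
    """

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def add(self, name: str, members, description: str = "") -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene-set name {name!r}")
        members = list(dict.fromkeys(members))
        if not members:
            raise FormatError(f"gene set {name!r} is empty")
        self.sets[name] = members
        self.descriptions[name] = description


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV into a table of (sample, gene, variant_classification).

    Lines starting with ``#`` (e.g. ``#version``) are skipped.  Column order
    is irrelevant; only the three required columns are consumed.
    """
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty MAF file") from None
    for col in MAF_REQUIRED_COLUMNS:
        if col not in raw.columns:
            raise FormatError(f"{path}: missing required MAF column {col!r}")
    table = pd.DataFrame({
        "sample": raw["Tumor_Sample_Barcode"].astype(str).str.strip(),
        "gene": raw["Hugo_Symbol"].astype(str).str.strip(),
        "variant_classification": raw["Variant_Classification"].astype(str).str.strip(),
    })
    if len(table) == 0:
        raise FormatError(f"{path}: MAF file has a header but no records")
    bad = (table["sample"] == "") | (table["gene"] == "")
    if bad.any():
        raise FormatError(f"{path}: {int(bad.sum())} record(s) with empty sample or gene")
    unknown = sorted(set(table["variant_classification"]) - MAF_VOCABULARY)
    if unknown:
        logger.warning("%s: %d variant classification label(s) outside the MAF "
                       "vocabulary retained: %s", path, len(unknown), unknown)
    return table.reset_index(drop=True)


def write_maf(table: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "Hugo_Symbol": table["gene"],
        "Tumor_Sample_Barcode": table["sample"],
        "Variant_Classification": table["variant_classification"],
    })
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample expression TSV (first column = gene tokens).

    Duplicate gene rows are collapsed by the per-cell maximum (logged).
    Non-numeric cells are a format error reported with their coordinates.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          na_filter=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty expression file") from None
    if raw.shape[1] == 0 or raw.shape[0] == 0:
        raise FormatError(f"{path}: expression matrix has no samples or no genes")
    raw.index = raw.index.astype(str).str.strip()
    raw.index.name = "gene"
    raw.columns = raw.columns.astype(str).str.strip()
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample column(s) {dup}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna().to_numpy()
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-numeric expression value {raw.iat[r, c]!r} at "
            f"gene {raw.index[r]!r}, sample {raw.columns[c]!r}")
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        logger.warning("%s: %d duplicated gene row(s) collapsed by maximum", path, n_dup)
        values = values.groupby(level=0, sort=False).max()
    if not np.isfinite(values.to_numpy()).all():
        raise FormatError(f"{path}: non-finite expression value(s)")
    return values


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read a standard GMT file: name <tab> description <tab> members..."""
    collection = GeneSetCollection()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT line has "
                                  f"{len(fields)} field(s), expected >= 3")
            name, description = fields[0].strip(), fields[1]
            members = [g.strip() for g in fields[2:] if g.strip()]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            if name in collection.sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
            collection.add(name, members, description)
    if len(collection) == 0:
        raise FormatError(f"{path}: GMT file contains no gene sets")
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as handle:
        for name, members in collection.items():
            desc = collection.descriptions.get(name, "")
            handle.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# Clinical
# ---------------------------------------------------------------------------

_CLINICAL_OPTIONAL = ("age", "stage", "os_time", "os_event", "response", "immune_infiltrated")

_SEX_MAP = {"male": "male", "m": "male", "female": "female", "f": "female"}
_RESPONSE_MAP = {"responder": "responder", "response": "responder", "r": "responder",
                 "nonresponder": "nonresponder", "non-responder": "nonresponder",
                 "non_responder": "nonresponder", "nr": "nonresponder"}
_BOOL_MAP = {"true": True, "1": True, "yes": True, "t": True,
             "false": False, "0": False, "no": False, "f": False}


def read_clinical(path) -> pd.DataFrame:
    """Read the per-sample clinical TSV, indexed by sample id.

    Sex is mapped case-insensitively onto {male, female}; rows whose sample
    or sex cannot be parsed are dropped with a warning; unparseable optional
    fields become missing.  Duplicate sample ids are a format error.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty clinical file") from None
    if "sample" not in raw.columns or "sex" not in raw.columns:
        raise FormatError(f"{path}: clinical table requires 'sample' and 'sex' columns")

    samples = raw["sample"].astype(str).str.strip()
    sex = raw["sex"].astype(str).str.strip().str.lower().map(_SEX_MAP)
    keep = (samples != "") & samples.notna() & sex.notna()
    if (~keep).any():
        logger.warning("%s: dropped %d row(s) with unparseable sample or sex",
                       path, int((~keep).sum()))
    if samples[keep].duplicated().any():
        dup = samples[keep][samples[keep].duplicated()].tolist()
        raise FormatError(f"{path}: duplicate sample id(s) {dup}")

    table = pd.DataFrame(index=pd.Index(samples[keep], name="sample"))
    table["sex"] = sex[keep].to_numpy()

    def col(name):
        if name in raw.columns:
            return raw.loc[keep, name].astype(str).str.strip()
        return None

    age = col("age")
    table["age"] = (pd.to_numeric(age, errors="coerce").to_numpy()
                    if age is not None else np.nan)
    stage = col("stage")
    if stage is not None:
        table["stage"] = stage.replace({"": None, "nan": None, "NA": None}).to_numpy()
    else:
        table["stage"] = None
    os_time = col("os_time")
    table["os_time"] = (pd.to_numeric(os_time, errors="coerce").to_numpy()
                        if os_time is not None else np.nan)
    os_event = col("os_event")
    if os_event is not None:
        ev = pd.to_numeric(os_event, errors="coerce")
        ev[~ev.isin([0, 1])] = np.nan
        table["os_event"] = ev.to_numpy(dtype=float)
    else:
        table["os_event"] = np.nan
    response = col("response")
    if response is not None:
        table["response"] = response.str.lower().map(_RESPONSE_MAP).to_numpy()
    else:
        table["response"] = None
    infiltrated = col("immune_infiltrated")
    if infiltrated is not None:
        flags = infiltrated.str.lower().map(_BOOL_MAP)
        table["immune_infiltrated"] = flags.fillna(True).astype(bool).to_numpy()
    else:
        logger.warning("%s: no immune_infiltrated column; assuming all samples "
                       "pass the infiltration filter", path)
        table["immune_infiltrated"] = True
    return table


def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample")
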