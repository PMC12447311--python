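"""Tabular input/output and the shared data model.

Everything the pipeline reads or writes is a plain-text table: wide
protein-quantification matrices (one row per protein accession, one
intensity column per sample) with a sample-metadata sheet, UniProt-style
tab-exported annotations, and a small receptor->ligand knowledgebase.
Accessions are the primary key throughout; gene symbols are display-only.

Missing or undetected intensities are stored as exact ``0.0`` — empty
cells, ``NA``/``NaN`` strings and literal zeros all collapse onto that
single "not detected" sentinel, mirroring how label-free proteomics
treats proteins that are undetected or too low for quantification.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rlmatch")

__all__ = [
    "Condition",
    "SampleMeta",
    "QuantMatrix",
    "AnnotationSet",
    "LigandKBEntry",
    "DataError",
    "DIALECTS",
    "read_quant_table",
    "write_quant_table",
    "read_annotations",
    "write_annotations",
    "read_ligand_kb",
    "write_ligand_kb",
    "default_ligand_kb",
    "default_receptor_classes",
    "default_annotation_rules",
    "write_report",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data (CLI exit code 3)."""


class Condition(str, Enum):
    """The two cell states being compared.

    ``A`` is the reference state (display name "hiPSC"), ``B`` the
    differentiated state (display name "iN"). All statistics are
    reported in the B-over-A direction.
    """

    A = "stateA"
    B = "stateB"

    @property
    def display_name(self) -> str:
        return _DISPLAY_NAMES[self]

    @classmethod
    def parse(cls, text: str) -> "Condition":
        key = str(text).strip().lower()
        aliases = {
            "statea": cls.A,
            "a": cls.A,
            "hipsc": cls.A,
            "ipsc": cls.A,
            "ips": cls.A,
            "stateb": cls.B,
            "b": cls.B,
            "in": cls.B,
            "neuron": cls.B,
        }
        try:
            return aliases[key]
        except KeyError:
            raise DataError(f"unrecognized condition label: {text!r}") from None


_DISPLAY_NAMES = {Condition.A: "hiPSC", Condition.B: "iN"}

#: Column-sum target for normalized matrices (relative iBAQ fractions).
NORMALIZATION_CONSTANT = 1.0

#: Sentinel ligand name for candidates without a knowledgebase entry.
UNMATCHED = "(unmatched)"


@dataclass(frozen=True)
class SampleMeta:
    """One quantified sample: which cell state, which culture batch."""

    sample_id: str
    condition: Condition
    batch: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise DataError("sample_id must be non-empty")
        object.__setattr__(self, "condition", Condition(self.condition))


def _check_samples(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DataError(f"duplicate sample_id(s): {dupes}")
    # paired-by-batch design: every batch label must occur in both states
    by_cond: dict[Condition, set[str]] = {Condition.A: set(), Condition.B: set()}
    for s in samples:
        by_cond[s.condition].add(s.batch)
    if by_cond[Condition.A] != by_cond[Condition.B]:
        only_a = sorted(by_cond[Condition.A] - by_cond[Condition.B])
        only_b = sorted(by_cond[Condition.B] - by_cond[Condition.A])
        raise DataError(
            "every batch must appear in both conditions; "
            f"only in {Condition.A.display_name}: {only_a}, "
            f"only in {Condition.B.display_name}: {only_b}"
        )


@dataclass
class QuantMatrix:
    """Protein x sample intensity matrix with sample metadata.

    Intensities are raw iBAQ values (arbitrary units) until
    :func:`rlmatch.quant.normalize_ibaq` rescales each sample column to
    sum to 1 (relative iBAQ); ``normalized`` records which state the
    matrix is in. Zeros are the "not detected" sentinel and survive
    normalization as zeros.
    """

    accessions: list[str]
    gene_symbols: list[str]
    intensities: np.ndarray
    samples: list[SampleMeta]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n_prot, n_samp = self.intensities.shape
        if len(self.accessions) != n_prot:
            raise DataError(
                f"{len(self.accessions)} accessions for {n_prot} matrix rows"
            )
        if len(self.gene_symbols) != n_prot:
            raise DataError("gene_symbols must parallel accessions")
        if len(self.samples) != n_samp:
            raise DataError(f"{len(self.samples)} samples for {n_samp} matrix columns")
        if len(set(self.accessions)) != len(self.accessions):
            raise DataError("accessions must be unique")
        if not np.isfinite(self.intensities).all():
            raise DataError("intensities must be finite")
        if (self.intensities < 0).any():
            raise DataError("intensities must be non-negative")
        _check_samples(self.samples)
        if self.normalized:
            sums = self.intensities.sum(axis=0)
            if not np.allclose(sums, NORMALIZATION_CONSTANT, rtol=1e-9, atol=0):
                raise DataError("normalized matrix columns must sum to 1")

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def batches(self) -> list[str]:
        """Batch labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.batch, None)
        return list(seen)

    def sample_indices(self, condition: Condition) -> list[int]:
        return [i for i, s in enumerate(self.samples) if s.condition == condition]

    def condition_values(self, condition: Condition) -> np.ndarray:
        """Protein x replicate submatrix for one condition (batch order)."""
        order = {b: k for k, b in enumerate(self.batches)}
        idx = sorted(self.sample_indices(condition), key=lambda i: order[self.samples[i].batch])
        return self.intensities[:, idx]

    def accession_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.accessions)}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities, columns=[s.sample_id for s in self.samples]
        )
        df.insert(0, "gene_symbol", self.gene_symbols)
        df.insert(0, "accession", self.accessions)
        return df


@dataclass
class AnnotationSet:
    """Per-accession annotation flags used by the surfaceome funnel.

    Flags are nested: neurotrophic receptor => growth-factor receptor =>
    membrane protein. The invariant is enforced at construction; inputs
    violating it are a hard error (the funnel would otherwise be
    ill-defined).
    """

    table: pd.DataFrame  # indexed by accession
    source_version: str = "unversioned"

    _COLUMNS = (
        "gene_symbol",
        "is_membrane",
        "is_growth_factor_receptor",
        "is_neurotrophic_receptor",
        "subcellular_locations",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self._COLUMNS if c not in self.table.columns]
        if missing:
            raise DataError(f"annotation table missing columns: {missing}")
        if self.table.index.has_duplicates:
            dupes = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise DataError(f"duplicate annotation accessions: {dupes}")
        nt = self.table["is_neurotrophic_receptor"].astype(bool)
        gf = self.table["is_growth_factor_receptor"].astype(bool)
        mem = self.table["is_membrane"].astype(bool)
        if (nt & ~gf).any():
            bad = sorted(self.table.index[nt & ~gf])
            raise DataError(
                f"neurotrophic receptors not flagged growth-factor receptor: {bad}"
            )
        if (gf & ~mem).any():
            bad = sorted(self.table.index[gf & ~mem])
            raise DataError(f"growth-factor receptors not flagged membrane: {bad}")
        # canonical dtypes and row order (accession-sorted: order-invariant)
        self.table = self.table.assign(
            is_membrane=mem, is_growth_factor_receptor=gf, is_neurotrophic_receptor=nt
        ).sort_index()

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, accession: str) -> bool:
        return accession in self.table.index

    def membrane_accessions(self) -> set[str]:
        return set(self.table.index[self.table["is_membrane"]])

    def growth_factor_receptor_accessions(self) -> set[str]:
        return set(self.table.index[self.table["is_growth_factor_receptor"]])

    def neurotrophic_receptor_accessions(self) -> set[str]:
        return set(self.table.index[self.table["is_neurotrophic_receptor"]])

    def gene_symbol(self, accession: str) -> str:
        return str(self.table.at[accession, "gene_symbol"])


@dataclass(frozen=True)
class LigandKBEntry:
    """One curated receptor->ligand pairing.

    ``ligand_available`` records whether the ligand is commercially
    obtainable as a recombinant supplement; ``notes`` carries free-text
    metadata such as the working concentration.
    """

    receptor_symbol: str
    receptor_accession: str
    ligand_name: str
    ligand_available: bool = True
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.receptor_symbol or not self.ligand_name:
            raise DataError("receptor_symbol and ligand_name must be non-empty")


def _check_kb(entries: Sequence[LigandKBEntry]) -> None:
    pairs = [(e.receptor_symbol, e.ligand_name) for e in entries]
    if len(set(pairs)) != len(pairs):
        dupes = sorted({p for p in pairs if pairs.count(p) > 1})
        raise DataError(f"duplicate (receptor, ligand) pair(s) in knowledgebase: {dupes}")


# ---------------------------------------------------------------------------
# quantification tables
# ---------------------------------------------------------------------------

#: Column-name conventions per input dialect. ``intensity`` is a template
#: applied to each declared sample_id.
DIALECTS: dict[str, dict[str, str]] = {
    "generic_tsv": {
        "accession": "accession",
        "gene_symbol": "gene_symbol",
        "intensity": "{sample_id}",
    },
    "proteome_discoverer_export": {
        "accession": "Accession",
        "gene_symbol": "Gene Symbol",
        "intensity": "iBAQ: {sample_id}",
    },
}

_NA_STRINGS = {"", "na", "nan", "n/a", "none", "null"}


def _read_table(path: Path) -> pd.DataFrame:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_sample_meta(meta_path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet (columns: sample_id, condition, batch)."""
    meta_path = Path(meta_path)
    df = _read_table(meta_path)
    required = {"sample_id", "condition", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"sample metadata missing columns: {sorted(missing)}")
    samples = [
        SampleMeta(row.sample_id, Condition.parse(row.condition), str(row.batch))
        for row in df.itertuples()
    ]
    _check_samples(samples)
    return samples


def _parse_intensity(cell: str, row_label: str, col: str) -> float:
    text = str(cell).strip()
    if text.lower() in _NA_STRINGS:
        return 0.0
    try:
        value = float(text)
    except ValueError:
        raise DataError(
            f"non-numeric intensity {cell!r} at row {row_label!r}, column {col!r}"
        ) from None
    if np.isnan(value):
        return 0.0
    if value < 0:
        raise DataError(
            f"negative intensity {value} at row {row_label!r}, column {col!r}"
        )
    return value


def read_quant_table(
    path: str | Path,
    meta_path: str | Path,
    dialect: str = "generic_tsv",
) -> QuantMatrix:
    """Read a wide quantification table plus its sample sheet.

    Rows sharing an accession are merged by summing their intensities
    (protein groups split across rows), with a logged warning. Empty
    cells, ``NA`` and 0 all become the 0.0 "not detected" sentinel.

    Raises :class:`DataError` if a declared sample has no intensity
    column, or any cell is negative or non-numeric.
    """
    if dialect not in DIALECTS:
        raise DataError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    conv = DIALECTS[dialect]
    path = Path(path)
    df = _read_table(path)
    if conv["accession"] not in df.columns:
        raise DataError(
            f"{path.name}: missing accession column {conv['accession']!r}"
        )
    samples = read_sample_meta(meta_path)
    col_for = {s.sample_id: conv["intensity"].format(sample_id=s.sample_id) for s in samples}
    absent = [c for c in col_for.values() if c not in df.columns]
    if absent:
        raise DataError(f"{path.name}: missing intensity column(s) {absent}")

    accs = df[conv["accession"]].astype(str).str.strip()
    if (accs == "").any():
        raise DataError(f"{path.name}: empty accession value")
    if conv["gene_symbol"] in df.columns:
        symbols = df[conv["gene_symbol"]].astype(str).str.strip()
    else:
        symbols = accs.copy()

    values = np.empty((len(df), len(samples)), dtype=float)
    for j, s in enumerate(samples):
        col = col_for[s.sample_id]
        for i, cell in enumerate(df[col].tolist()):
            values[i, j] = _parse_intensity(cell, accs.iloc[i], col)

    if accs.duplicated().any():
        dupes = sorted(accs[accs.duplicated()].unique())
        logger.warning(
            "merged %d duplicate accession row(s) by summing intensities: %s",
            len(dupes),
            ", ".join(dupes[:10]) + ("..." if len(dupes) > 10 else ""),
        )
        warnings.warn(
            f"duplicate accessions merged by summing: {dupes[:10]}", stacklevel=2
        )
        merged = pd.DataFrame(values)
        merged.insert(0, "__acc", accs.values)
        summed = merged.groupby("__acc", sort=False).sum()
        first_symbol = (
            pd.DataFrame({"__acc": accs.values, "sym": symbols.values})
            .groupby("__acc", sort=False)
            .first()["sym"]
        )
        accessions = list(summed.index)
        gene_symbols = [first_symbol[a] for a in accessions]
        values = summed.to_numpy(dtype=float)
    else:
        accessions = accs.tolist()
        gene_symbols = symbols.tolist()

    return QuantMatrix(
        accessions=accessions,
        gene_symbols=gene_symbols,
        intensities=values,
        samples=samples,
        normalized=False,
    )


def write_quant_table(
    qm: QuantMatrix, path: str | Path, meta_path: str | Path
) -> None:
    """Write a QuantMatrix in the ``generic_tsv`` dialect plus sample sheet."""
    path, meta_path = Path(path), Path(meta_path)
    qm.to_frame().to_csv(path, sep="\t", index=False)
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in qm.samples],
            "condition": [s.condition.value for s in qm.samples],
            "batch": [s.batch for s in qm.samples],
        }
    ).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

_ANNOT_COLUMN_ALIASES = {
    "accession": ["accession", "Entry", "entry"],
    "gene_symbol": ["gene_symbol", "Gene Names", "Gene names", "gene names"],
    "keywords": ["keywords", "Keywords"],
    "subcellular_location": [
        "subcellular_location",
        "Subcellular location [CC]",
        "Subcellular location",
    ],
}


def _find_column(df: pd.DataFrame, logical: str, required: bool) -> str | None:
    for name in _ANNOT_COLUMN_ALIASES[logical]:
        if name in df.columns:
            return name
    if required:
        raise DataError(
            f"annotation table missing {logical} column "
            f"(accepted names: {_ANNOT_COLUMN_ALIASES[logical]})"
        )
    return None


@dataclass(frozen=True)
class AnnotationRule:
    """One declarative flag rule: substring match on a field sets a flag."""

    field: str  # "keyword" or "location"
    pattern: str  # case-insensitive substring
    flag: str  # annotation flag column to set


def default_annotation_rules() -> list[AnnotationRule]:
    """Load the packaged keyword/location -> flag rule file."""
    text = resources.files("rlmatch.data").joinpath("annotation_rules.tsv").read_text()
    return _parse_rules(text)


def _parse_rules(text: str) -> list[AnnotationRule]:
    rules = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DataError(f"malformed rule line: {line!r}")
        fld, pattern, flag = (p.strip() for p in parts)
        if fld not in ("keyword", "location"):
            raise DataError(f"rule field must be keyword|location, got {fld!r}")
        if flag not in (
            "is_membrane",
            "is_growth_factor_receptor",
            "is_neurotrophic_receptor",
        ):
            raise DataError(f"unknown rule flag {flag!r}")
        rules.append(AnnotationRule(fld, pattern, flag))
    return rules


def read_annotation_rules(path: str | Path) -> list[AnnotationRule]:
    return _parse_rules(Path(path).read_text())


def default_receptor_classes() -> pd.DataFrame:
    """Packaged curated receptor-class list (symbol, accession, class).

    ``class`` is ``growth_factor`` or ``neurotrophic``; the curated list
    overrides keyword-derived flags wherever both apply.
    """
    with resources.files("rlmatch.data").joinpath("receptor_classes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, comment="#")
    required = {"gene_symbol", "accession", "receptor_class"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"receptor class list missing columns: {sorted(missing)}")
    return df


def read_annotations(
    path: str | Path,
    rules: Sequence[AnnotationRule] | None = None,
    curated: pd.DataFrame | None = None,
    source_version: str = "unversioned",
) -> AnnotationSet:
    """Read a UniProt-style tab export into an :class:`AnnotationSet`.

    Membrane flags come from the declarative rule file (keyword
    "Membrane", or a subcellular location containing "Cell membrane" /
    "Plasma membrane" by default). Receptor-class flags come from keyword
    rules plus the packaged curated list; the curated list wins on
    conflict. Flags are propagated upward so the nesting invariant
    (neurotrophic => growth-factor receptor => membrane) always holds.
    """
    path = Path(path)
    df = _read_table(path)
    if df.empty:
        raise DataError(f"{path.name}: annotation file has no rows")
    acc_col = _find_column(df, "accession", required=True)
    sym_col = _find_column(df, "gene_symbol", required=False)
    kw_col = _find_column(df, "keywords", required=False)
    loc_col = _find_column(df, "subcellular_location", required=False)

    if rules is None:
        rules = default_annotation_rules()
    if curated is None:
        curated = default_receptor_classes()

    accs = df[acc_col].astype(str).str.strip()
    if accs.duplicated().any():
        dupes = sorted(accs[accs.duplicated()].unique())
        raise DataError(f"duplicate annotation accessions: {dupes}")
    n = len(df)
    symbols = (
        df[sym_col].astype(str).str.strip().str.split().str[0].fillna("")
        if sym_col
        else accs
    )
    keywords = df[kw_col].astype(str) if kw_col else pd.Series([""] * n)
    locations = df[loc_col].astype(str) if loc_col else pd.Series([""] * n)

    flags = {
        "is_membrane": np.zeros(n, dtype=bool),
        "is_growth_factor_receptor": np.zeros(n, dtype=bool),
        "is_neurotrophic_receptor": np.zeros(n, dtype=bool),
    }
    for rule in rules:
        haystack = keywords if rule.field == "keyword" else locations
        hit = haystack.str.contains(rule.pattern, case=False, regex=False).to_numpy()
        flags[rule.flag] |= hit

    # curated receptor classes override keyword-derived flags
    by_acc = {str(a).strip(): str(c).strip() for a, c in zip(curated["accession"], curated["receptor_class"])}
    by_sym = {str(s).strip().upper(): str(c).strip() for s, c in zip(curated["gene_symbol"], curated["receptor_class"])}
    for i, (a, s) in enumerate(zip(accs, symbols)):
        cls = by_acc.get(a) or by_sym.get(str(s).upper())
        if cls == "growth_factor":
            flags["is_growth_factor_receptor"][i] = True
        elif cls == "neurotrophic":
            flags["is_growth_factor_receptor"][i] = True
            flags["is_neurotrophic_receptor"][i] = True

    # propagate upward so nesting holds
    flags["is_growth_factor_receptor"] |= flags["is_neurotrophic_receptor"]
    flags["is_membrane"] |= flags["is_growth_factor_receptor"]

    loc_lists = [
        [p.strip() for p in str(loc).split(";") if p.strip()] for loc in locations
    ]
    table = pd.DataFrame(
        {
            "gene_symbol": symbols.to_numpy(),
            "is_membrane": flags["is_membrane"],
            "is_growth_factor_receptor": flags["is_growth_factor_receptor"],
            "is_neurotrophic_receptor": flags["is_neurotrophic_receptor"],
            "subcellular_locations": loc_lists,
        },
        index=pd.Index(accs.to_numpy(), name="accession"),
    )
    return AnnotationSet(table=table, source_version=source_version)


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    """Write an AnnotationSet to TSV (round-trips via read_annotation_set)."""
    df = ann.table.copy()
    df["subcellular_locations"] = ["; ".join(v) for v in df["subcellular_locations"]]
    df.to_csv(Path(path), sep="\t", index=True, index_label="accession")


def read_annotation_set(path: str | Path, source_version: str = "unversioned") -> AnnotationSet:
    """Read back the flag-level TSV written by :func:`write_annotations`."""
    df = pd.read_csv(Path(path), sep="\t", dtype=str, keep_default_na=False)
    if "accession" not in df.columns:
        raise DataError("annotation set file missing accession column")
    table = pd.DataFrame(
        {
            "gene_symbol": df["gene_symbol"].astype(str).to_numpy(),
            "is_membrane": (df["is_membrane"].str.lower() == "true").to_numpy(),
            "is_growth_factor_receptor": (
                df["is_growth_factor_receptor"].str.lower() == "true"
            ).to_numpy(),
            "is_neurotrophic_receptor": (
                df["is_neurotrophic_receptor"].str.lower() == "true"
            ).to_numpy(),
            "subcellular_locations": [
                [p.strip() for p in str(v).split(";") if p.strip()]
                for v in df["subcellular_locations"]
            ],
        },
        index=pd.Index(df["accession"].astype(str).to_numpy(), name="accession"),
    )
    return AnnotationSet(table=table, source_version=source_version)


# ---------------------------------------------------------------------------
# ligand knowledgebase
# ---------------------------------------------------------------------------

_KB_FIELDS = ("receptor_symbol", "receptor_accession", "ligand_name", "ligand_available", "notes")


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "y"):
        return True
    if text in ("false", "0", "no", "n", ""):
        return False
    raise DataError(f"cannot parse boolean value {value!r}")


def read_ligand_kb(path: str | Path) -> list[LigandKBEntry]:
    """Read a receptor->ligand knowledgebase from TSV or JSON.

    One receptor may map to several ligands (one entry each); a repeated
    (receptor, ligand) pair is a hard error.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if not isinstance(records, list):
            raise DataError("ligand KB JSON must be a list of objects")
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
        missing = {"receptor_symbol", "ligand_name"} - set(df.columns)
        if missing:
            raise DataError(f"ligand KB missing columns: {sorted(missing)}")
        records = df.to_dict(orient="records")
    entries = [
        LigandKBEntry(
            receptor_symbol=str(r["receptor_symbol"]).strip(),
            receptor_accession=str(r.get("receptor_accession", "")).strip(),
            ligand_name=str(r["ligand_name"]).strip(),
            ligand_available=_parse_bool(r.get("ligand_available", True)),
            notes=str(r.get("notes", "")).strip(),
        )
        for r in records
    ]
    _check_kb(entries)
    return entries


def write_ligand_kb(entries: Sequence[LigandKBEntry], path: str | Path) -> None:
    _check_kb(list(entries))
    pd.DataFrame([{f: getattr(e, f) for f in _KB_FIELDS} for e in entries]).to_csv(
        Path(path), sep="\t", index=False
    )


def default_ligand_kb() -> list[LigandKBEntry]:
    """The packaged neurotrophic receptor->ligand knowledgebase."""
    with resources.as_file(
        resources.files("rlmatch.data").joinpath("ligand_kb.tsv")
    ) as p:
        return read_ligand_kb(p)


# ---------------------------------------------------------------------------
# result reports
# ---------------------------------------------------------------------------

def write_report(
    recommendations: Sequence["object"],
    differential_table: pd.DataFrame,
    out_dir: str | Path,
    formats: Iterable[str] = ("tsv", "json"),
) -> list[Path]:
    """Write recommendation and differential tables deterministically.

    Rows are ordered (rank, accession) for recommendations and by
    accession for the differential table; column order is fixed, so two
    writes of the same inputs are byte-identical.
    """
    from .rlm import RLMRecommendation  # cycle-free: only for field order

    out_dir = Path(out_dir)
    formats = set(formats)
    bad = formats - {"tsv", "json"}
    if bad:
        raise DataError(f"unknown report formats: {sorted(bad)}")
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise DataError(f"output directory not writable: {out_dir} ({exc})") from exc

    rec_df = pd.DataFrame(
        [
            {f: getattr(r, f) for f in RLMRecommendation.field_order()}
            for r in recommendations
        ],
        columns=list(RLMRecommendation.field_order()),
    )
    if len(rec_df):
        rec_df["rationale_flags"] = [
            ",".join(sorted(v)) for v in rec_df["rationale_flags"]
        ]
        rec_df = rec_df.sort_values(["rank", "receptor_accession"], kind="mergesort")
    else:
        rec_df["rationale_flags"] = rec_df.get("rationale_flags", pd.Series(dtype=str))

    diff_df = differential_table.sort_values("accession", kind="mergesort").reset_index(
        drop=True
    )

    written: list[Path] = []
    if "tsv" in formats:
        for name, df in (("recommendations", rec_df), ("differential", diff_df)):
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
    if "json" in formats:
        for name, df in (("recommendations", rec_df), ("differential", diff_df)):
            p = out_dir / f"{name}.json"
            p.write_text(df.to_json(orient="records", indent=2, double_precision=15) + "\n")
            written.append(p)
    return written
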