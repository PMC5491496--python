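"""Domain types and I/O for TaqMan low-density-array (TLDA) qPCR data.

The central container is :class:`CtMatrix`, a samples x assays table of
cycle-threshold (Ct) values with an explicit detectability mask and a
plate (A/B card) assignment per assay.  Lower Ct means higher abundance.

Conventions
-----------
* Sequence coordinates are 1-based and inclusive; the miRNA *seed* is
  nucleotides 2-8 of the mature sequence.
* Undetectable qPCR wells are recorded in tables as the literal
  ``Undetermined`` (or an empty cell) and stored as NaN with a ``False``
  detectability flag.  A display ceiling (e.g. Ct 40) may be imputed for
  plotting only, never for statistics.
* DNA alphabet input (``T``) is silently converted to RNA (``U``);
  lower-case input is accepted and upper-cased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CtMatrix",
    "SampleInfo",
    "MiRNAAnnotation",
    "EndoControlSet",
    "read_ct_table",
    "write_ct_table",
    "read_sample_table",
    "write_sample_table",
    "read_annotation_table",
    "write_annotation_table",
    "read_fasta",
    "clean_rna",
    "reverse_complement",
    "extract_seed",
    "scan_seed_sites",
]

Stage = Literal["raw", "delta_ct", "global_centered"]
_STAGES = ("raw", "delta_ct", "global_centered")
_RNA_ALPHABET = frozenset("ACGU")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")

ANNOTATION_COLUMNS = (
    "assay_id",
    "mirbase_acc",
    "plate",
    "chromosome",
    "strand",
    "mature_seq",
    "seed",
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtMatrix:
    """Ct values (samples x assays) with detectability mask and plate map.

    Parameters
    ----------
    values
        Float DataFrame indexed by sample id with assay ids as columns.
        NaN marks a missing/undetectable well.
    detect_mask
        Boolean DataFrame of the same shape; ``True`` = detectable.
        Must be ``False`` wherever ``values`` is NaN.
    plate_of_assay
        Series mapping every assay id to plate ``"A"`` or ``"B"``.
    stage
        One of ``raw``, ``delta_ct`` (median-normalised) or
        ``global_centered`` (per-sample global-mean centred).  The only
        permitted transitions are raw -> delta_ct and raw -> global_centered.
    """

    values: pd.DataFrame
    detect_mask: pd.DataFrame
    plate_of_assay: pd.Series
    stage: Stage = "raw"

    def __post_init__(self) -> None:
        v, m = self.values, self.detect_mask
        if v.index.has_duplicates:
            raise ValueError("duplicate sample ids in CtMatrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate assay ids in CtMatrix")
        if not (v.index.equals(m.index) and v.columns.equals(m.columns)):
            raise ValueError("values and detect_mask are not aligned")
        if v.size and bool(
            (m.to_numpy(dtype=bool) & np.isnan(v.to_numpy(dtype=float))).any()
        ):
            raise ValueError("detect_mask must be False wherever value is missing")
        missing_plate = set(v.columns) - set(self.plate_of_assay.index)
        if missing_plate:
            raise ValueError(f"assays without plate assignment: {sorted(missing_plate)}")
        bad = set(self.plate_of_assay.loc[list(v.columns)]) - {"A", "B"}
        if bad:
            raise ValueError(f"plate labels must be 'A' or 'B', got {sorted(bad)}")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    # -- convenience -------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def assays(self) -> list[str]:
        return list(self.values.columns)

    def plate(self, assay: str) -> str:
        return str(self.plate_of_assay.loc[assay])

    def subset_assays(self, assays: Sequence[str]) -> "CtMatrix":
        assays = list(assays)
        return replace(
            self,
            values=self.values.loc[:, assays],
            detect_mask=self.detect_mask.loc[:, assays],
            plate_of_assay=self.plate_of_assay.loc[assays],
        )

    def derive(self, values: pd.DataFrame, stage: Stage) -> "CtMatrix":
        """Return a transformed copy, enforcing the stage transition rule."""
        if self.stage != "raw" or stage not in ("delta_ct", "global_centered"):
            raise ValueError(
                f"invalid stage transition {self.stage!r} -> {stage!r}; "
                "only raw->delta_ct and raw->global_centered are allowed"
            )
        return replace(self, values=values, stage=stage)


@dataclass(frozen=True)
class SampleInfo:
    """Per-subject metadata: diagnostic group and tissue covariates."""

    sample_id: str
    group: Literal["control", "case"]
    age: float  # years
    sex: Literal["F", "M"]
    pmi: float  # postmortem interval, hours
    ph: float  # brain pH
    rin: float  # RNA integrity number

    def __post_init__(self) -> None:
        if self.group not in ("control", "case"):
            raise ValueError(f"group must be control|case, got {self.group!r}")
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F|M, got {self.sex!r}")
        if not self.age > 0:
            raise ValueError("age must be positive")
        if self.pmi < 0:
            raise ValueError("pmi must be non-negative")
        if not 5 < self.ph < 9:
            raise ValueError(f"brain pH {self.ph} outside (5, 9)")
        if not 1 <= self.rin <= 10:
            raise ValueError(f"RIN {self.rin} outside [1, 10]")


@dataclass(frozen=True)
class MiRNAAnnotation:
    """Per-assay annotation: accession, plate, genomic location, seed."""

    assay_id: str
    mirbase_acc: str
    plate: Literal["A", "B"]
    chromosome: str
    strand: Literal["sense", "antisense"]
    mature_seq: str | None = None
    seed: str | None = None

    def __post_init__(self) -> None:
        if self.plate not in ("A", "B"):
            raise ValueError(f"plate must be A|B, got {self.plate!r}")
        if self.strand not in ("sense", "antisense"):
            raise ValueError(f"strand must be sense|antisense, got {self.strand!r}")
        if self.mature_seq is not None:
            object.__setattr__(self, "mature_seq", clean_rna(self.mature_seq))
        if self.seed is not None:
            object.__setattr__(self, "seed", clean_rna(self.seed))
            if len(self.seed) != 7:
                raise ValueError(f"seed must be 7 nt, got {self.seed!r}")
        if self.mature_seq is not None and self.seed is not None:
            if extract_seed(self.mature_seq) != self.seed:
                raise ValueError(
                    f"{self.assay_id}: seed {self.seed} does not equal "
                    f"nucleotides 2-8 of the mature sequence"
                )


@dataclass(frozen=True)
class EndoControlSet:
    """Endogenous normaliser small RNAs plus the plant negative control."""

    normalizers: tuple[str, ...] = ("U6", "RNU44", "RNU48")
    negative_control_id: str = "ath-miR-159a"

    def __post_init__(self) -> None:
        if not self.normalizers:
            raise ValueError("normalizer set must be non-empty")


# ---------------------------------------------------------------------------
# Ct table I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","


def _parse_ct(raw: object, row: int) -> float:
    """Parse one Ct cell; 'Undetermined'/blank -> NaN, junk -> error."""
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    text = str(raw).strip()
    if text == "" or text.lower() in ("undetermined", "nan", "na"):
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"non-numeric Ct value {text!r} at data row {row}") from None


def read_ct_table(
    path: str | Path,
    dialect: Literal["wide", "long"],
    plate_of_assay: dict[str, str] | pd.Series | None = None,
) -> CtMatrix:
    """Read a raw Ct table from CSV/TSV.

    ``wide`` tables have assays in rows (first column ``assay_id``, then one
    column per sample); ``long`` tables have columns ``sample``, ``assay``,
    ``ct`` and optionally ``plate``.  Cells that are blank or read
    ``Undetermined`` become undetectable.  Assays with no plate information
    default to plate A.
    """
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        df = pd.read_csv(path, sep=sep, dtype=str)
        if df.columns[0] != "assay_id":
            raise ValueError("wide Ct table must start with an 'assay_id' column")
        if df["assay_id"].duplicated().any():
            dup = df.loc[df["assay_id"].duplicated(), "assay_id"].iloc[0]
            raise ValueError(f"duplicate assay id {dup!r} in wide table")
        assays = df["assay_id"].tolist()
        samples = list(df.columns[1:])
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample columns in wide table")
        vals = np.empty((len(samples), len(assays)))
        for j, (_, row) in enumerate(df.iterrows()):
            for i, s in enumerate(samples):
                vals[i, j] = _parse_ct(row[s], j + 2)
        values = pd.DataFrame(vals, index=samples, columns=assays)
    elif dialect == "long":
        df = pd.read_csv(path, sep=sep, dtype=str)
        required = {"sample", "assay", "ct"}
        if not required.issubset(df.columns):
            raise ValueError(f"long Ct table must have columns {sorted(required)}")
        dup = df.duplicated(subset=["sample", "assay"])
        if dup.any():
            r = df.loc[dup].iloc[0]
            raise ValueError(f"duplicate (sample, assay) pair: {r['sample']},{r['assay']}")
        df = df.assign(_ct=[_parse_ct(v, i + 2) for i, v in enumerate(df["ct"])])
        values = df.pivot(index="sample", columns="assay", values="_ct").astype(float)
        # preserve file order of first appearance rather than pandas' sort
        values = values.loc[
            pd.unique(df["sample"]).tolist(), pd.unique(df["assay"]).tolist()
        ]
        values.index.name = None
        values.columns.name = None
        if "plate" in df.columns and plate_of_assay is None:
            plate_of_assay = (
                df.drop_duplicates("assay").set_index("assay")["plate"].astype(str)
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if plate_of_assay is None:
        plate = pd.Series("A", index=values.columns)
    else:
        plate = pd.Series(plate_of_assay).astype(str)
        plate = plate.reindex(values.columns).fillna("A")
    mask = values.notna()
    return CtMatrix(values=values, detect_mask=mask, plate_of_assay=plate, stage="raw")


def write_ct_table(ct: CtMatrix, path: str | Path, dialect: Literal["wide", "long"]) -> Path:
    """Write a Ct table; undetectable wells are emitted as ``Undetermined``.

    Round-trips losslessly with :func:`read_ct_table` for matrices whose
    undetectable cells carry no stored value (the generator's convention).
    """
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        out = ct.values.T.copy().astype(object)
        out = out.where(pd.notna(out), "Undetermined")
        out.insert(0, "assay_id", out.index)
        out.to_csv(path, sep=sep, index=False)
    elif dialect == "long":
        rows = []
        for s in ct.samples:
            for a in ct.assays:
                v = ct.values.at[s, a]
                rows.append(
                    {
                        "sample": s,
                        "assay": a,
                        "ct": "Undetermined" if pd.isna(v) else repr(float(v)),
                        "plate": ct.plate(a),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# sample / annotation table I/O
# ---------------------------------------------------------------------------


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    """Read per-sample metadata (sample_id, group, age, pmi, sex, ph, rin)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return [
        SampleInfo(
            sample_id=str(r.sample_id),
            group=str(r.group),
            age=float(r.age),
            sex=str(r.sex),
            pmi=float(r.pmi),
            ph=float(r.ph),
            rin=float(r.rin),
        )
        for r in df.itertuples()
    ]


def write_sample_table(samples: Iterable[SampleInfo], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame([s.__dict__ for s in samples]).to_csv(path, sep=_sep_for(path), index=False)
    return path


def samples_to_frame(samples: Iterable[SampleInfo]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in samples]).set_index("sample_id")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    return df


def read_annotation_table(path: str | Path) -> list[MiRNAAnnotation]:
    """Read the assay annotation table (columns exactly ANNOTATION_COLUMNS)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if tuple(df.columns) != ANNOTATION_COLUMNS:
        raise ValueError(
            f"annotation table must have columns {list(ANNOTATION_COLUMNS)}, "
            f"got {list(df.columns)}"
        )
    out = []
    for r in df.itertuples():
        out.append(
            MiRNAAnnotation(
                assay_id=r.assay_id,
                mirbase_acc=r.mirbase_acc,
                plate=r.plate,
                chromosome=str(r.chromosome),
                strand=r.strand,
                mature_seq=None if pd.isna(r.mature_seq) else r.mature_seq,
                seed=None if pd.isna(r.seed) else r.seed,
            )
        )
    return out


def write_annotation_table(annotations: Iterable[MiRNAAnnotation], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([a.__dict__ for a in annotations], columns=list(ANNOTATION_COLUMNS))
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read sequences (e.g. 3' UTRs) from FASTA, as RNA uppercase strings."""
    return {rec.id: clean_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# sequence utilities
# ---------------------------------------------------------------------------


def clean_rna(seq: str) -> str:
    """Uppercase, convert DNA T to RNA U, and validate the alphabet."""
    s = seq.strip().upper().replace("T", "U")
    bad = set(s) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotides {sorted(bad)} in sequence")
    return s


def reverse_complement(seq: str) -> str:
    return clean_rna(seq).translate(_RNA_COMPLEMENT)[::-1]


def extract_seed(mature_seq: str) -> str:
    """Return the 7-nt seed: nucleotides 2-8 (1-based, inclusive)."""
    s = clean_rna(mature_seq)
    if len(s) < 8:
        raise ValueError(f"mature sequence shorter than 8 nt: {mature_seq!r}")
    return s[1:8]


def scan_seed_sites(seed: str, utr: str) -> list[tuple[int, str]]:
    """Scan a 3' UTR for canonical seed-match sites.

    Site types follow the standard canonical taxonomy:

    * ``8mer``     - reverse complement of seed nt 2-8 of the mature miRNA
      (the whole 7-nt seed) followed by an A on the UTR.
    * ``7mer-m8``  - reverse complement of the whole seed, without the A1.
    * ``7mer-A1``  - reverse complement of mature nt 2-7 followed by an A.

    Returns 1-based start positions on the UTR.  Overlapping sites are all
    reported, but a window already counted as an 8mer is not re-reported as
    the 7mer site(s) it contains.
    """
    seed = clean_rna(seed)
    if len(seed) != 7:
        raise ValueError(f"seed must be 7 nt, got {len(seed)}")
    utr = clean_rna(utr)
    if len(utr) < 7:
        raise ValueError("UTR shorter than 7 nt")

    match_m8 = reverse_complement(seed)  # 7 nt
    match_8mer = match_m8 + "A"
    match_a1 = reverse_complement(seed[:6]) + "A"  # mature nt 2-7 + A

    sites: list[tuple[int, str]] = []
    starts_8mer = set()
    for i in range(len(utr) - 8 + 1):
        if utr[i : i + 8] == match_8mer:
            sites.append((i + 1, "8mer"))
            starts_8mer.add(i + 1)
    for i in range(len(utr) - 7 + 1):
        pos = i + 1
        window = utr[i : i + 7]
        if window == match_m8 and pos not in starts_8mer:
            sites.append((pos, "7mer-m8"))
        if window == match_a1 and (pos - 1) not in starts_8mer:
            sites.append((pos, "7mer-A1"))
    sites.sort()
    return sites
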