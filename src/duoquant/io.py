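"""Readers and writers for every external artifact of the pipeline.

The peptide-evidence dialect is a flat, hand-writable TSV rather than
pepXML/mzIdentML: search-engine outputs vary widely and the downstream
analysis needs only a handful of fields per peptide-spectrum match (PSM).
Column-to-pepXML mapping:

=================  =========================================================
evidence column    pepXML concept
=================  =========================================================
sample_id          ``msms_run_summary`` (one LC-MS/MS run per sample)
engine             ``search_engine`` (``A`` = peak-area arm, ``B`` = spectral
                   -count arm)
peptide_seq        ``search_hit/@peptide``
proteins           ``@protein`` plus ``alternative_protein`` entries,
                   semicolon-separated (shared peptides list every accession)
charge             ``assumed_charge``
score              primary search score (engine A: XCorr-like)
observed_mass      ``precursor_neutral_mass``
theoretical_mass   ``calc_neutral_pep_mass``
peak_area          precursor extracted-ion-chromatogram area (engine A only;
                   empty for engine B, where abundance = PSM row count)
is_decoy           hit against the shuffled decoy database (0/1)
=================  =========================================================

All files are UTF-8 text with "." as the decimal separator.  Readers never
silently drop rows: every input row either comes back validated or is
reported with its line number.
"""

from __future__ import annotations

import io as _stdio
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


#: canonical evidence columns, in writing order
EVIDENCE_COLUMNS = [
    "sample_id",
    "engine",
    "peptide_seq",
    "proteins",
    "charge",
    "score",
    "observed_mass",
    "theoretical_mass",
    "peak_area",
    "is_decoy",
]

_PEPTIDE_RE = re.compile(r"^[A-Z]+$")
_TRUE = {"1", "true", "True", "TRUE", "yes"}
_FALSE = {"0", "false", "False", "FALSE", "no", ""}

#: group labels recognised as the control (non-muscle-invasive) role
CONTROL_ALIASES = ("control", "ctrl", "pTa", "NMIBC")


@dataclass(frozen=True)
class SampleDesign:
    """Two-group sample layout (control = pTa-like, case = pT2+-like)."""

    groups: Mapping[str, str]  # sample_id -> group label
    control_label: str
    case_label: str

    def __post_init__(self) -> None:
        labels = set(self.groups.values())
        if labels != {self.control_label, self.case_label}:
            raise FormatError(
                f"design labels {sorted(labels)} do not match "
                f"control={self.control_label!r}/case={self.case_label!r}"
            )
        if not self.control_samples or not self.case_samples:
            raise FormatError("both groups must be nonempty")

    @property
    def control_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == self.control_label]

    @property
    def case_samples(self) -> list[str]:
        return [s for s, g in self.groups.items() if g == self.case_label]

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    @property
    def n_control(self) -> int:
        return len(self.control_samples)

    @property
    def n_case(self) -> int:
        return len(self.case_samples)

    def swapped(self) -> "SampleDesign":
        """Exchange the control/case roles (for symmetry checks)."""
        return SampleDesign(dict(self.groups), self.case_label, self.control_label)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset


@dataclass
class GeneSetCollection:
    """Named identifier sets (GMT content) keyed by set name."""

    sets: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"empty file: {path}") from None
    if df.empty and df.columns.empty:
        raise FormatError(f"empty file: {path}")
    return df


def read_evidence(path, engine_id: str) -> tuple[pd.DataFrame, list[str]]:
    """Read a per-sample peptide-evidence TSV for one engine.

    Returns ``(rows, errors)`` where *rows* is a validated DataFrame (proteins
    parsed into tuples, numerics typed) and *errors* lists rejected rows as
    ``"line N: message"`` strings.  ``len(rows) + len(errors)`` equals the
    number of data rows in the file.

    Raises
    ------
    FormatError
        If the file is empty, a mandatory column is missing, or the engine
        column contradicts *engine_id* throughout.
    """
    if engine_id not in ("A", "B"):
        raise ValueError(f"engine_id must be 'A' or 'B', got {engine_id!r}")
    df = _read_tsv(path)
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    if df.empty:
        raise FormatError(f"empty file (header only): {path}")

    errors: list[str] = []
    rows = []
    for i, rec in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        rec = dict(zip(df.columns, rec))
        problems = []
        if rec["engine"] != engine_id:
            problems.append(f"engine {rec['engine']!r} != {engine_id!r}")
        if not _PEPTIDE_RE.match(rec["peptide_seq"]):
            problems.append(f"invalid peptide_seq {rec['peptide_seq']!r}")
        accs = tuple(a for a in rec["proteins"].split(";") if a)
        if not accs:
            problems.append("empty protein accession list")
        num = {}
        for col in ("charge", "score", "observed_mass", "theoretical_mass"):
            try:
                num[col] = float(rec[col])
            except ValueError:
                problems.append(f"unparseable {col} {rec[col]!r}")
        if "charge" in num:
            if num["charge"] < 1 or num["charge"] != int(num["charge"]):
                problems.append(f"charge must be a positive integer, got {rec['charge']!r}")
        for col in ("observed_mass", "theoretical_mass"):
            if col in num and num[col] <= 0:
                problems.append(f"{col} must be > 0")
        if rec["is_decoy"] in _TRUE:
            decoy = True
        elif rec["is_decoy"] in _FALSE:
            decoy = False
        else:
            problems.append(f"unparseable is_decoy {rec['is_decoy']!r}")
            decoy = None
        area = np.nan
        if rec["peak_area"] != "":
            try:
                area = float(rec["peak_area"])
            except ValueError:
                problems.append(f"unparseable peak_area {rec['peak_area']!r}")
            else:
                if area < 0:
                    problems.append("peak_area must be >= 0")
        elif engine_id == "A" and not decoy:
            problems.append("engine A row lacks peak_area")
        if problems:
            errors.append(f"line {line}: " + "; ".join(problems))
            continue
        rows.append(
            (
                rec["sample_id"],
                engine_id,
                rec["peptide_seq"],
                accs,
                int(num["charge"]),
                num["score"],
                num["observed_mass"],
                num["theoretical_mass"],
                area,
                decoy,
            )
        )
    out = pd.DataFrame(rows, columns=EVIDENCE_COLUMNS)
    _check_decoy_disjoint(out)
    return out, errors


def _check_decoy_disjoint(ev: pd.DataFrame) -> None:
    """Decoy rows must never share accessions with target rows."""
    if ev.empty:
        return
    decoy_accs = set().union(*ev.loc[ev["is_decoy"], "proteins"]) if ev["is_decoy"].any() else set()
    target_accs = set().union(*ev.loc[~ev["is_decoy"], "proteins"]) if (~ev["is_decoy"]).any() else set()
    shared = decoy_accs & target_accs
    if shared:
        raise FormatError(f"decoy and target rows share accessions: {sorted(shared)[:5]}")


def read_design(path, control_label: str | None = None) -> SampleDesign:
    """Read the sample-design TSV (columns ``sample_id``, ``group``).

    The control role defaults to a recognised alias (control/ctrl/pTa/NMIBC)
    or, failing that, the lexicographically first label.
    """
    df = _read_tsv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column(s): {col}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id {dup!r}")
    labels = sorted(set(df["group"]))
    if len(labels) != 2:
        raise FormatError(f"design must define exactly two groups, got {labels}")
    if control_label is None:
        control_label = next((a for a in CONTROL_ALIASES if a in labels), labels[0])
    if control_label not in labels:
        raise FormatError(f"control label {control_label!r} not in design groups {labels}")
    case_label = next(l for l in labels if l != control_label)
    return SampleDesign(dict(zip(df["sample_id"], df["group"])), control_label, case_label)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB member...)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    coll = GeneSetCollection()
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {line_no}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
            if name in coll.sets:
                raise FormatError(f"line {line_no}: duplicate gene-set name {name!r}")
            uniq = frozenset(members)
            if len(uniq) < len(members):
                coll.warnings.append(f"line {line_no}: duplicate members in {name!r} deduplicated")
            coll.sets[name] = GeneSet(name, desc, uniq)
    if not coll.sets:
        raise FormatError(f"empty GMT file: {path}")
    return coll


def read_fasta(path) -> dict[str, str]:
    """Read a protein FASTA into ``{accession: uppercased sequence}``.

    The accession is the first whitespace-delimited token of the header; for
    pipe-delimited UniProt headers (``sp|P12345|NAME``) the middle token.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        parts = token.split("|")
        acc = parts[1] if len(parts) >= 3 and parts[1] else token
        if acc in out:
            raise FormatError(f"duplicate accession {acc!r}")
        out[acc] = str(rec.seq).upper()
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def read_mapping(path) -> dict[str, str]:
    """Read a two-column accession -> identifier mapping TSV (no header)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            fields = raw.split("\t")
            if len(fields) != 2:
                raise FormatError(f"line {line_no}: mapping line needs exactly 2 fields")
            out[fields[0]] = fields[1]
    return out


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, metadata: Mapping | None = None) -> dict[str, Path]:
    """Write result tables as TSV with a ``#``-prefixed run-metadata header.

    Column order is preserved as given; reruns with identical inputs produce a
    byte-identical data section (metadata lines may differ only through the
    values supplied in *metadata*).
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc
    header_lines = [f"# {k}: {v}" for k, v in (metadata or {}).items()]
    paths = {}
    for name, table in tables.items():
        path = out_dir / f"{name}.tsv"
        buf = _stdio.StringIO()
        for line in header_lines:
            buf.write(line + "\n")
        table.to_csv(buf, sep="\t", index=False)
        path.write_text(buf.getvalue(), encoding="utf-8")
        paths[name] = path
    return paths


def read_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_evidence(ev: pd.DataFrame, path) -> Path:
    """Write an evidence DataFrame in the documented TSV dialect."""
    out = ev.copy()
    out["proteins"] = [";".join(p) for p in out["proteins"]]
    out["is_decoy"] = out["is_decoy"].astype(int)
    out["peak_area"] = out["peak_area"].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    path = Path(path)
    out.to_csv(path, sep="\t", index=False, columns=EVIDENCE_COLUMNS)
    return path


def write_design(design: SampleDesign, path) -> Path:
    pd.DataFrame({"sample_id": design.samples, "group": [design.groups[s] for s in design.samples]}).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def write_fasta(seqs: Mapping[str, str], path) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        for acc, seq in seqs.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return Path(path)
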