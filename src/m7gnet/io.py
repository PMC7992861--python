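"""Readers/writers for site tables, association lists and labeled matrices.

All tabular inputs are plain delimited text (comma-separated by default, with
a tab-separated fallback detected from the header line).  Matrices are stored
with row and column labels, the dialect used for distributed site-site and
disease-disease similarity tables.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, FormatError, ValidationError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
CONFIDENCE_LEVELS = ("high", "medium", "low")

#: site table columns beyond the required site_id / ref_seq
_OPTIONAL_COLUMNS = (
    "chrom",
    "position",
    "strand",
    "host_gene",
    "alt_seq",
    "association_level",
    "confidence_level",
)


@dataclass
class SiteRecord:
    """One m7G site with its site-centered reference sequence.

    Genomic coordinates are 1-based and strand-explicit; they are carried as
    metadata only and no computation depends on them.
    """

    site_id: str
    ref_seq: str
    chrom: str | None = None
    position: int | None = None
    strand: str | None = None
    host_gene: str | None = None
    alt_seq: str | None = None
    association_level: float | None = None
    confidence_level: str | None = None
    site_centered: bool = False

    def validate(self, seq_length: int | None = None) -> "SiteRecord":
        """Check sequence contracts; raise :class:`ValidationError` naming the site."""
        seq = self.ref_seq
        if seq_length is not None and len(seq) != seq_length:
            raise ValidationError(
                f"site {self.site_id!r}: ref_seq has length {len(seq)}, "
                f"expected {seq_length}"
            )
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"site {self.site_id!r}: ref_seq contains non-ACGT "
                f"character(s) {sorted(bad)}"
            )
        if self.site_centered:
            if len(seq) % 2 == 0:
                raise ValidationError(
                    f"site {self.site_id!r}: site-centered sequence must have "
                    f"odd length, got {len(seq)}"
                )
            center = seq[len(seq) // 2]
            if center != "G":
                raise ValidationError(
                    f"site {self.site_id!r}: center base is {center!r}, "
                    "expected G for a site-centered sequence"
                )
        if self.confidence_level is not None and self.confidence_level not in CONFIDENCE_LEVELS:
            raise ValidationError(
                f"site {self.site_id!r}: unknown confidence level "
                f"{self.confidence_level!r}"
            )
        if self.association_level is not None and not 0.0 <= self.association_level <= 1.0:
            raise ValidationError(
                f"site {self.site_id!r}: association_level "
                f"{self.association_level} outside [0, 1]"
            )
        return self


@dataclass
class DiseaseRecord:
    """A disease with its ontology identifier (e.g. a DOID) and name."""

    disease_id: str
    name: str = ""


@dataclass
class AssociationMatrix:
    """Binary site-disease association matrix with ordered labels."""

    sites: list[str]
    diseases: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = len(self.sites), len(self.diseases)
        if self.values.shape != (m, n):
            raise ContractError(
                f"association matrix shape {self.values.shape} does not match "
                f"{m} sites x {n} diseases"
            )
        if len(set(self.sites)) != m or len(set(self.diseases)) != n:
            raise ValidationError("site/disease labels must be unique")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValidationError("association matrix entries must be 0 or 1")

    @property
    def n_known(self) -> int:
        return int(self.values.sum())

    def known_pairs(self) -> list[tuple[int, int]]:
        """(site index, disease index) of every known association."""
        return [tuple(ij) for ij in np.argwhere(self.values == 1.0)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.diseases)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AssociationMatrix":
        return cls(
            sites=[str(s) for s in frame.index],
            diseases=[str(d) for d in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_site_table(
    path: str | Path,
    seq_length: int | None = 41,
    fasta: str | Path | None = None,
    site_centered: bool = False,
) -> list[SiteRecord]:
    """Read a delimited site table into validated :class:`SiteRecord` objects.

    The table must name at least a ``site_id`` column and either a ``ref_seq``
    column or a companion FASTA file keyed by site_id.  Row order is
    preserved.  Sequences are upper-cased before validation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    if "site_id" not in table.columns:
        raise FormatError(f"{path}: missing required column 'site_id'")
    seqs: dict[str, str] = {}
    if fasta is not None:
        seqs = read_fasta(fasta)
    elif "ref_seq" not in table.columns:
        raise FormatError(
            f"{path}: missing 'ref_seq' column and no companion FASTA given"
        )
    records = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        site_id = d["site_id"]
        seq = d.get("ref_seq") if pd.notna(d.get("ref_seq", None)) else None
        if seq is None:
            if site_id not in seqs:
                raise ValidationError(f"site {site_id!r}: no sequence in FASTA")
            seq = seqs[site_id]
        kwargs = {}
        for col in _OPTIONAL_COLUMNS:
            val = d.get(col)
            if val is None or (isinstance(val, float) and math.isnan(val)) or pd.isna(val):
                continue
            if col == "position":
                val = int(val)
            elif col == "association_level":
                val = float(val)
            elif col == "confidence_level":
                val = str(val).lower()
            kwargs[col] = val
        rec = SiteRecord(
            site_id=str(site_id),
            ref_seq=str(seq).upper(),
            site_centered=site_centered,
            **kwargs,
        )
        records.append(rec.validate(seq_length))
    return records


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` mapping.

    Uses Biopython when available, otherwise a minimal parser; sequences are
    upper-cased.
    """
    path = Path(path)
    try:
        from Bio import SeqIO  # type: ignore

        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    except ImportError:  # pragma: no cover - biopython is a soft dependency
        seqs: dict[str, list[str]] = {}
        name = None
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    seqs[name] = []
                elif name is not None:
                    seqs[name].append(line.upper())
        return {k: "".join(v) for k, v in seqs.items()}


def filter_variant_pairs(
    records: Sequence[SiteRecord],
    min_level: float = 0.8,
    required_confidence: str = "high",
) -> list[SiteRecord]:
    """Keep records at the required confidence with association level strictly above ``min_level``.

    The confidence filter is applied first, then the strict (>) level
    threshold, so a high-confidence record at exactly ``min_level`` is
    dropped.  Input order is preserved and the operation is idempotent.
    """
    if required_confidence not in CONFIDENCE_LEVELS:
        raise ContractError(f"unknown confidence level {required_confidence!r}")
    confident = [r for r in records if r.confidence_level == required_confidence]
    for r in confident:
        if r.association_level is None:
            raise ValidationError(
                f"site {r.site_id!r}: association_level required for filtering"
            )
    return [r for r in confident if r.association_level > min_level]


def read_association_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (site_id, disease_id) association list."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sniff_sep(path), dtype=str)
    cols = list(table.columns)
    if len(cols) < 2:
        raise FormatError(f"{path}: expected two columns (site_id, disease_id)")
    return [(str(s), str(d)) for s, d in zip(table[cols[0]], table[cols[1]])]


def build_association_matrix(
    pairs: Iterable[tuple[str, str]],
    sites: Sequence[str],
    diseases: Sequence[str],
) -> AssociationMatrix:
    """Build the binary association matrix from (site_id, disease_id) pairs.

    Entry (i, j) is 1 iff the pair occurs in ``pairs``; duplicates collapse to
    a single 1 with a logged warning, and unknown labels raise.
    """
    site_index = {s: i for i, s in enumerate(sites)}
    disease_index = {d: j for j, d in enumerate(diseases)}
    values = np.zeros((len(sites), len(diseases)))
    seen = set()
    for s, d in pairs:
        if s not in site_index:
            raise ContractError(f"unknown site id {s!r} in association pair")
        if d not in disease_index:
            raise ContractError(f"unknown disease id {d!r} in association pair")
        if (s, d) in seen:
            logger.warning("duplicate association pair (%s, %s) collapsed", s, d)
        seen.add((s, d))
        values[site_index[s], disease_index[d]] = 1.0
    return AssociationMatrix(list(map(str, sites)), list(map(str, diseases)), values)


def read_matrix(
    path: str | Path,
    expect_square: bool = False,
    expect_symmetric: bool = False,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Read a labeled matrix (first row = column labels, first column = row labels).

    When ``expect_symmetric``, the matrix is checked for symmetry within
    ``tol`` (after which it is exactly symmetrized as (M + M^T)/2) and label
    agreement between rows and columns.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    frame.index = frame.index.map(str)
    frame.columns = frame.columns.map(str)
    if (expect_square or expect_symmetric) and frame.shape[0] != frame.shape[1]:
        raise ValidationError(
            f"{path}: expected a square matrix, got shape {frame.shape}"
        )
    if expect_symmetric:
        if list(frame.index) != list(frame.columns):
            raise ValidationError(f"{path}: row and column labels differ")
        values = frame.to_numpy(dtype=float)
        gap = float(np.abs(values - values.T).max()) if values.size else 0.0
        if gap > tol:
            raise ValidationError(
                f"{path}: asymmetry {gap:.3g} exceeds tolerance {tol:.3g}"
            )
        frame.loc[:, :] = (values + values.T) / 2.0
    return frame


def write_matrix(matrix: pd.DataFrame | AssociationMatrix, path: str | Path) -> None:
    """Write a labeled matrix as delimited text re-readable by :func:`read_matrix`."""
    if isinstance(matrix, AssociationMatrix):
        matrix = matrix.to_frame()
    values = matrix.to_numpy(dtype=float)
    if values.size and not np.isfinite(values).all():
        raise ValidationError(f"refusing to write non-finite entries to {path}")
    matrix.to_csv(path, float_format="%.12g")
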