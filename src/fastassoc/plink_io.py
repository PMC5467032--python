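"""Reading and writing PLINK 1.x binary filesets (.bed/.bim/.fam).

Genotypes are stored as A1-allele dosages in an ``int8`` matrix of shape
(n_subjects, n_markers); missing calls are the sentinel :data:`MISSING`.
Decoding goes straight from the SNP-major byte stream into a marker-contiguous
(Fortran-ordered) dosage matrix, so each marker column is a contiguous slice
ready for regression without an intermediate full-matrix transpose.

Two-bit encoding (PLINK 1.x standard, low-order bits first within a byte):

======  ==================  =========
code    genotype            A1 dosage
======  ==================  =========
``00``  homozygous A1       2
``01``  missing             MISSING
``10``  heterozygous        1
``11``  homozygous A2       0
======  ==================  =========
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "PlinkFormatError",
    "MarkerInfo",
    "SampleInfo",
    "GenotypeStudy",
    "read_bed",
    "write_bed",
    "to_design_matrix",
]

#: Sentinel dosage value for a missing genotype call.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# two-bit code -> dosage, in code order 00, 01, 10, 11
_DOSAGE_FROM_CODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
# dosage + 1 -> two-bit code (index 0 is MISSING = -1)
_CODE_FROM_DOSAGE = np.array([0b01, 0b11, 0b10, 0b00], dtype=np.uint8)

# byte -> 4 dosages (low-order pair first)
_BYTE_LUT = np.empty((256, 4), dtype=np.int8)
for _b in range(256):
    for _k in range(4):
        _BYTE_LUT[_b, _k] = _DOSAGE_FROM_CODE[(_b >> (2 * _k)) & 0b11]
del _b, _k


def _ext(prefix: Path, suffix: str) -> Path:
    # append, not replace: a prefix like "study.v2" keeps its dot
    return prefix.parent / (prefix.name + suffix)


class PlinkFormatError(ValueError):
    """Raised when a fileset violates the PLINK 1.x binary format."""


@dataclass
class MarkerInfo:
    """One .bim record: marker metadata in file order."""

    chrom: str
    id: str
    cm: float
    bp: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("marker id must be non-empty")
        if self.bp < 0:
            raise ValueError(f"marker {self.id}: bp must be >= 0, got {self.bp}")


@dataclass
class SampleInfo:
    """One .fam record: subject metadata in file order."""

    fid: str
    iid: str
    pat: str = "0"
    mat: str = "0"
    sex: int = 0
    pheno: str = "-9"


@dataclass(eq=False)
class GenotypeStudy:
    """An N x M allele-dosage matrix with marker and sample metadata.

    ``dosage[i, j]`` is the A1-allele count of subject ``i`` at marker ``j``,
    one of {0, 1, 2, MISSING}.
    """

    dosage: np.ndarray
    markers: list[MarkerInfo] = field(repr=False)
    samples: list[SampleInfo] = field(repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if len(self.samples) != n or len(self.markers) != m:
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"{bad.sum()} dosage entries outside {{0,1,2,MISSING}}")

    @property
    def n_subjects(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeStudy):
            return NotImplemented
        return (
            np.array_equal(self.dosage, other.dosage)
            and self.markers == other.markers
            and self.samples == other.samples
        )


def _read_table(path: Path, n_cols: int, what: str) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != n_cols:
                raise PlinkFormatError(
                    f"{path}: line {ln} has {len(fields)} fields, expected {n_cols} ({what})"
                )
            rows.append(fields)
    return rows


def read_bim(path: os.PathLike | str) -> list[MarkerInfo]:
    """Read a .bim file (CHR ID CM BP A1 A2)."""
    rows = _read_table(Path(path), 6, ".bim record")
    return [
        MarkerInfo(chrom=r[0], id=r[1], cm=float(r[2]), bp=int(r[3]), a1=r[4], a2=r[5])
        for r in rows
    ]


def read_fam(path: os.PathLike | str) -> list[SampleInfo]:
    """Read a .fam file (FID IID PAT MAT SEX PHENO)."""
    rows = _read_table(Path(path), 6, ".fam record")
    samples = [
        SampleInfo(fid=r[0], iid=r[1], pat=r[2], mat=r[3], sex=int(float(r[4])), pheno=r[5])
        for r in rows
    ]
    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.fid, s.iid)
        if key in seen:
            raise PlinkFormatError(f"{path}: duplicate FID/IID pair {key}")
        seen.add(key)
    return samples


def read_bed(prefix: os.PathLike | str) -> GenotypeStudy:
    """Read a PLINK binary fileset ``prefix``.{bed,bim,fam}.

    The .bed must be SNP-major (mode byte 0x01).  Each marker's byte block is
    decoded directly into the corresponding column of the dosage matrix;
    sample order follows the .fam file.
    """
    prefix = Path(prefix)
    markers = read_bim(_ext(prefix, ".bim"))
    samples = read_fam(_ext(prefix, ".fam"))
    n, m = len(samples), len(markers)

    raw = np.fromfile(_ext(prefix, ".bed"), dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:2]) != _BED_MAGIC:
        got = raw[:2].tobytes().hex() if raw.size >= 2 else raw.tobytes().hex()
        raise PlinkFormatError(
            f"{_ext(prefix, '.bed')}: bad magic bytes 0x{got}, expected 0x6c1b"
        )
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(
            f"{_ext(prefix, '.bed')}: mode byte 0x{raw[2]:02x} is not "
            f"SNP-major (0x01); individual-major files are not supported"
        )
    bytes_per_marker = (n + 3) // 4
    expected = bytes_per_marker * m
    body = raw[3:]
    if body.size != expected:
        raise PlinkFormatError(
            f"{_ext(prefix, '.bed')}: {body.size} genotype bytes, expected "
            f"ceil({n}/4)*{m} = {expected} (truncated or padded file)"
        )
    # (m, bytes) -> (m, 4*bytes) dosages -> strided N x M view, marker-contiguous
    decoded = _BYTE_LUT[body.reshape(m, bytes_per_marker)].reshape(m, 4 * bytes_per_marker)
    dosage = decoded[:, :n].T
    return GenotypeStudy(dosage=dosage, markers=markers, samples=samples)


def write_bed(study: GenotypeStudy, prefix: os.PathLike | str) -> None:
    """Write ``study`` as a SNP-major PLINK fileset ``prefix``.{bed,bim,fam}.

    Missing dosages are encoded as two-bit code ``01``; unused high-order bits
    in the final byte of each marker block are zero.
    """
    prefix = Path(prefix)
    n, m = study.n_subjects, study.n_markers
    bytes_per_marker = (n + 3) // 4

    codes = np.zeros((m, 4 * bytes_per_marker), dtype=np.uint8)
    codes[:, :n] = _CODE_FROM_DOSAGE[study.dosage.T.astype(np.int16) + 1]
    codes[:, n:] = 0  # pad slots -> zero bits
    packed = (
        codes[:, 0::4]
        | (codes[:, 1::4] << 2)
        | (codes[:, 2::4] << 4)
        | (codes[:, 3::4] << 6)
    )
    with open(_ext(prefix, ".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_BED_SNP_MAJOR]))
        packed.astype(np.uint8).tofile(fh)

    with open(_ext(prefix, ".bim"), "w") as fh:
        for mk in study.markers:
            cm = f"{mk.cm:g}"
            fh.write(f"{mk.chrom}\t{mk.id}\t{cm}\t{mk.bp}\t{mk.a1}\t{mk.a2}\n")
    with open(_ext(prefix, ".fam"), "w") as fh:
        for s in study.samples:
            fh.write(f"{s.fid} {s.iid} {s.pat} {s.mat} {s.sex} {s.pheno}\n")


def to_design_matrix(
    study: GenotypeStudy, missing_policy: str = "error"
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Densify the dosage matrix for regression, resolving missing calls.

    Parameters
    ----------
    missing_policy
        ``"error"``: raise if any call is missing (the fast path assumes
        complete data).  ``"drop_per_marker"``: leave missing cells as NaN and
        return, per marker, the subject indices to exclude from that marker's
        fit (PLINK's exact-mode semantics).  ``"mean_impute"``: replace each
        missing cell with the marker's mean dosage over observed subjects.

    Returns
    -------
    (X, masks)
        ``X`` is the float64 N x M dosage matrix.  ``masks`` maps marker index
        to the array of subject indices with a missing call at that marker;
        markers with complete data are absent from the dict.
    """
    if missing_policy not in ("error", "drop_per_marker", "mean_impute"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    miss = study.dosage == MISSING
    n_miss = int(miss.sum())
    if missing_policy == "error":
        if n_miss:
            raise ValueError(
                f"{n_miss} missing genotype call(s) present; the 'error' policy "
                f"requires complete data (use drop_per_marker or mean_impute)"
            )
        return study.dosage.astype(np.float64), {}

    X = study.dosage.astype(np.float64)
    masks: dict[int, np.ndarray] = {}
    if n_miss:
        cols = np.unique(np.nonzero(miss)[1])
        for j in cols:
            rows = np.nonzero(miss[:, j])[0]
            if missing_policy == "mean_impute":
                obs = np.delete(study.dosage[:, j], rows)
                X[rows, j] = obs.mean() if obs.size else 0.0
            else:
                masks[int(j)] = rows
                X[rows, j] = np.nan
    return X, masks
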