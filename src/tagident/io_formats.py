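"""Standard-format I/O (MGF, FASTA, tabular results) and tryptic digestion.

Peptide coordinates are 0-based half-open throughout. The MGF reader keeps
only the subset of the format the pipeline needs: BEGIN IONS/END IONS blocks
with TITLE, PEPMASS, CHARGE and peak lines.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .chem import STANDARD_RESIDUES, neutral_mass_from_mz

logger = logging.getLogger(__name__)

_ALLOWED = set(STANDARD_RESIDUES) | {"X"}


@dataclass(frozen=True)
class Peak:
    """A single (m/z, intensity) point of a centroided spectrum."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")


@dataclass
class Spectrum:
    """A tandem mass spectrum with precursor information.

    Peaks are stored sorted strictly ascending by m/z; duplicate m/z values
    are merged on construction by summing intensities.
    """

    peaks: list[Peak]
    precursor_mz: float
    precursor_charge: int
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor_charge must be >= 1")
        merged: dict[float, float] = {}
        for p in self.peaks:
            merged[p.mz] = merged.get(p.mz, 0.0) + p.intensity
        self.peaks = [Peak(mz, i) for mz, i in sorted(merged.items())]

    @property
    def precursor_neutral_mass(self) -> float:
        """Neutral (uncharged) mass of the intact precursor peptide."""
        return neutral_mass_from_mz(self.precursor_mz, self.precursor_charge)

    def mz_array(self) -> list[float]:
        return [p.mz for p in self.peaks]

    def intensity_array(self) -> list[float]:
        return [p.intensity for p in self.peaks]


@dataclass
class ProteinRecord:
    accession: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")


@dataclass(frozen=True)
class PeptideRecord:
    """A digestion product, locatable in its parent protein."""

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int = 0


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Parse an MGF file into a list of :class:`Spectrum`.

    Raises ``ValueError`` naming the (1-based) block index on malformed
    blocks and on blocks missing PEPMASS.
    """
    spectra: list[Spectrum] = []
    block = 0
    in_block = False
    title = ""
    pepmass: float | None = None
    charge = 0
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise ValueError(f"block {block}: nested BEGIN IONS (line {lineno})")
                block += 1
                in_block = True
                title, pepmass, charge, peaks = f"spectrum_{block}", None, 0, []
            elif line == "END IONS":
                if not in_block:
                    raise ValueError(f"END IONS without BEGIN IONS at line {lineno}")
                if pepmass is None:
                    raise ValueError(f"block {block}: missing PEPMASS")
                spectra.append(
                    Spectrum(
                        peaks=peaks,
                        precursor_mz=pepmass,
                        precursor_charge=charge or 2,
                        identifier=title,
                    )
                )
                in_block = False
            elif not in_block:
                continue  # header junk outside blocks is tolerated
            elif "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    m = re.match(r"(\d+)", value.strip().lstrip("+"))
                    if not m:
                        raise ValueError(f"block {block}: unparseable CHARGE {value!r}")
                    charge = int(m.group(1))
            else:
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(f"block {block}: malformed peak line {lineno}: {line!r}")
                try:
                    peaks.append(Peak(float(fields[0]), float(fields[1])))
                except ValueError as exc:
                    raise ValueError(f"block {block}: bad peak at line {lineno}") from exc
    if in_block:
        raise ValueError(f"block {block}: unterminated (missing END IONS)")
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.identifier}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for p in s.peaks:
                fh.write(f"{p.mz:.5f} {p.intensity:.4f}\n")
            fh.write("END IONS\n")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; non-standard letters are mapped to X."""
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = re.sub(r"\s", "", str(rec.seq)).upper()
        cleaned = "".join(c if c in _ALLOWED else "X" for c in seq)
        if cleaned != seq:
            bad = sorted({c for c in seq if c not in _ALLOWED})
            logger.warning("%s: non-standard letters %s mapped to X", rec.id, bad)
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=rec.description,
                sequence=cleaned,
            )
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.accession} {r.description}".rstrip() + "\n")
            for i in range(0, len(r.sequence), 60):
                fh.write(r.sequence[i : i + 60] + "\n")


def cleavage_sites(sequence: str) -> list[int]:
    """Tryptic cleavage positions: after K/R, not before P.

    Returned positions are indices where a cut occurs (peptide boundaries),
    excluding 0 and len(sequence).
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i + 1)
    return sites


def digest(
    protein: ProteinRecord,
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 30,
) -> list[PeptideRecord]:
    """In-silico tryptic digestion with up to ``missed_cleavages`` skips."""
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    peptides: list[PeptideRecord] = []
    for i in range(len(bounds) - 1):
        for skip in range(missed_cleavages + 1):
            j = i + 1 + skip
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            if min_len <= end - start <= max_len:
                peptides.append(
                    PeptideRecord(
                        sequence=seq[start:end],
                        parent_accession=protein.accession,
                        start=start,
                        end=end,
                        missed_cleavages=skip,
                    )
                )
    return peptides


def digest_database(
    proteins: Iterable[ProteinRecord],
    missed_cleavages: int = 2,
    min_len: int = 6,
    max_len: int = 30,
) -> list[PeptideRecord]:
    """Digest every protein; duplicate sequences are kept (distinct parents)."""
    out: list[PeptideRecord] = []
    for prot in proteins:
        out.extend(digest(prot, missed_cleavages, min_len, max_len))
    return out


#: Column order of the PSM result table written by :func:`write_psm_table`.
PSM_COLUMNS = [
    "spectrum_id",
    "peptide",
    "protein",
    "Ss",
    "Sc_log",
    "S",
    "D",
    "rank",
    "is_decoy",
    "tags",
]


def write_psm_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write PSM rows as TSV with the documented header line."""
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in PSM_COLUMNS) + "\n")


def iter_psm_table(path: str | Path) -> Iterator[dict]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            yield dict(zip(header, line.rstrip("\n").split("\t")))
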