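"""Read/write labelled FASTA and compute per-region sequence summaries.

Sequence headers carry the metadata as ``>sample_id|species|region`` (the
delimiter is configurable); alternatively a tab-separated sidecar can map
plain FASTA IDs to species and region.  Summaries report ungapped length
ranges, per-sequence GC extremes and the variable-site count over
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import SampleRecord, RegionAlignment, VALID_CHARS, UNAMBIGUOUS


class FastaParseError(ValueError):
    """A FASTA entry whose header or sequence cannot be interpreted."""


@dataclass(frozen=True)
class RegionSummary:
    """Per-region sequence summary: length and GC ranges, variable sites."""

    region: str
    n_samples: int
    length_min: int
    length_max: int
    gc_min: float
    gc_max: float
    variable_sites: int
    variable_pct: float


def _clean_sequence(raw: str, label: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_CHARS
    if bad:
        raise FastaParseError(
            f"entry {label!r}: invalid characters {sorted(bad)} in sequence"
        )
    return seq


def read_labelled_fasta(
    path: str | Path,
    delimiter: str = "|",
    region: str | None = None,
    species_map: dict[str, tuple[str, str]] | None = None,
) -> list[SampleRecord]:
    """Read species-labelled sequences from a FASTA file.

    Headers are parsed as ``sample_id<delim>species<delim>region``.  If
    ``species_map`` is given (sample_id -> (species, region), e.g. from a
    metadata sidecar), headers need only carry the sample ID.  ``region``,
    if given, restricts the result to that region.

    Raises
    ------
    FastaParseError
        On malformed headers, invalid sequence characters, or duplicate
        sample IDs within a region.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SampleRecord] = []
    seen: set[tuple[str, str]] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        header = entry.description or entry.id
        if species_map is not None:
            sid = entry.id
            if sid not in species_map:
                raise FastaParseError(f"sample {sid!r} absent from metadata sidecar")
            sp, reg = species_map[sid]
        else:
            parts = [p.strip() for p in header.split(delimiter)]
            if len(parts) < 3 or not all(parts[:3]):
                raise FastaParseError(
                    f"header {header!r}: expected sample_id{delimiter}species"
                    f"{delimiter}region"
                )
            sid, sp, reg = parts[0], parts[1], parts[2]
        if region is not None and reg != region:
            continue
        key = (sid, reg)
        if key in seen:
            raise FastaParseError(f"duplicate sample_id {sid!r} in region {reg!r}")
        seen.add(key)
        records.append(
            SampleRecord(
                sample_id=sid,
                species=sp,
                region=reg,
                sequence=_clean_sequence(str(entry.seq), sid),
            )
        )
    return records


def write_labelled_fasta(
    records, path: str | Path, delimiter: str = "|", width: int = 80
) -> None:
    """Write records as FASTA with ``sample_id|species|region`` headers."""
    out = [
        SeqRecord(
            Seq(r.sequence),
            id=delimiter.join([r.sample_id, r.species, r.region]),
            description="",
        )
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(out)


def read_metadata_sidecar(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a TSV sidecar (sample_id, species, region, [extras...])."""
    mapping: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if i == 1 and parts[0].lower() in ("sample_id", "sample", "id"):
                continue
            if len(parts) < 3:
                raise FastaParseError(f"sidecar line {i}: need >= 3 tab fields")
            mapping[parts[0]] = (parts[1], parts[2])
    return mapping


def gc_content(seq: str) -> float:
    """Percent G+C over unambiguous bases (gaps and N excluded)."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("gc_content undefined: no unambiguous bases")
    return 100.0 * (counts["G"] + counts["C"]) / total


def variable_sites(aln: RegionAlignment) -> tuple[int, float]:
    """Count alignment columns with >= 2 distinct unambiguous states.

    Gaps and N never make a column variable.  Returns (count, percent of
    columns).
    """
    ncols = aln.columns
    count = 0
    rows = [r.sequence for r in aln.records]
    for j in range(ncols):
        states = {row[j] for row in rows} & UNAMBIGUOUS
        if len(states) >= 2:
            count += 1
    return count, 100.0 * count / ncols


def per_species_gc(records) -> dict[str, float]:
    """Mean per-sequence GC within each species (percent)."""
    by_sp: dict[str, list[float]] = {}
    for r in records:
        by_sp.setdefault(r.species, []).append(gc_content(r.ungapped))
    return {sp: sum(v) / len(v) for sp, v in by_sp.items()}


def summarize_region(records, aln: RegionAlignment) -> RegionSummary:
    """Length range, GC range and variable sites for one region."""
    records = list(records)
    if not records:
        raise ValueError("summarize_region: no records")
    lengths = [r.ungapped_length for r in records]
    gcs = [gc_content(r.ungapped) for r in records]
    nvar, pvar = variable_sites(aln)
    return RegionSummary(
        region=aln.region,
        n_samples=len(records),
        length_min=min(lengths),
        length_max=max(lengths),
        gc_min=min(gcs),
        gc_max=max(gcs),
        variable_sites=nvar,
        variable_pct=pvar,
    )
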