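"""Core record types: one labelled sequence, and one per-region alignment."""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_CHARS = frozenset("ACGTN-")
UNAMBIGUOUS = frozenset("ACGT")


@dataclass(frozen=True)
class SampleRecord:
    """One sequence with its sample ID, species label and region tag.

    ``sequence`` is uppercase over the alphabet {A, C, G, T, N, -}; U is
    folded to T at parse time.  ``species`` is a free-form binomial string;
    ``region`` a short locus token (e.g. ``ITS2``).
    """

    sample_id: str
    species: str
    region: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.species:
            raise ValueError("species must be non-empty")
        if not self.region:
            raise ValueError("region must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.sample_id}: sequence must be non-empty")
        bad = set(self.sequence) - VALID_CHARS
        if bad:
            raise ValueError(
                f"{self.sample_id}: invalid sequence characters {sorted(bad)}; "
                "allowed: A C G T N -"
            )

    @property
    def ungapped(self) -> str:
        """Sequence with alignment gaps removed."""
        return self.sequence.replace("-", "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)


@dataclass
class RegionAlignment:
    """An alignment of all samples of one region (equal-length rows)."""

    region: str
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError(f"{self.region}: alignment needs >= 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(
                f"{self.region}: unequal aligned lengths {sorted(lengths)}"
            )
        regions = {r.region for r in self.records}
        if regions != {self.region}:
            raise ValueError(
                f"alignment region {self.region!r} vs record regions {sorted(regions)}"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"{self.region}: duplicate sample_ids {dupes}")

    @property
    def columns(self) -> int:
        return len(self.records[0].sequence)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def species_of(self) -> dict[str, str]:
        return {r.sample_id: r.species for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, sample_ids) -> "RegionAlignment":
        keep = set(sample_ids)
        return RegionAlignment(
            region=self.region,
            records=[r for r in self.records if r.sample_id in keep],
        )
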