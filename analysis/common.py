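"""Shared paths and loaders for the numbered analysis drivers."""

from pathlib import Path

from barcodegap.records import RegionAlignment
from barcodegap.seq_io import read_labelled_fasta
from barcodegap.study import STUDY_REGIONS

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def load_region(region: str) -> RegionAlignment:
    path = DATA / f"{region}.fasta"
    if not path.exists():
        raise SystemExit(
            f"{path} missing - run analysis/01_simulate.py first"
        )
    return RegionAlignment(
        region=region, records=read_labelled_fasta(path, region=region)
    )


def load_all() -> dict[str, RegionAlignment]:
    return {region: load_region(region) for region in STUDY_REGIONS}
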