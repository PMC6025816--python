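"""End-to-end evaluation of one or more candidate barcode regions.

Per region: sequence summaries -> K2P distance matrix -> divergence
parameters -> barcoding-gap histogram -> best-match and tree-based
identification.  Across regions: Wilcoxon signed-rank comparisons of
inter- and intraspecific divergence, and a final ranking by
identification efficiency.  All tables are emitted as TSV, trees as
Newick, and a JSON manifest records inputs, parameters and seed so a
run can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .records import RegionAlignment
from .seq_io import read_labelled_fasta, summarize_region, RegionSummary
from .distances import distance_matrix, DistanceMatrix
from .divergence import (
    divergence_summary,
    barcoding_gap,
    wilcoxon_signed_rank,
    pair_regions,
    DivergenceSummary,
    GapHistogram,
    WilcoxonResult,
    InsufficientDataError,
    InsufficientSpeciesError,
)
from .identification import (
    bootstrap_supports,
    best_match_identify,
    identification_rates,
    write_newick,
    IdentificationReport,
)

log = logging.getLogger("barcodegap")


@dataclass
class RunConfig:
    """Parameters of one evaluation run."""

    inputs: dict  # region -> FASTA path
    outdir: Path
    delimiter: str = "|"
    outgroup: tuple = ()
    replicates: int = 1000
    seed: int = 0
    alpha: float = 0.05
    bin_width: float = 0.01
    on_undefined: str = "drop-pair"
    tie_tolerance: float = 1e-9

    def __post_init__(self):
        if not self.inputs:
            raise ValueError("need >= 1 region input")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        self.outdir = Path(self.outdir)


@dataclass
class RegionResult:
    region: str
    summary: RegionSummary
    dm: DistanceMatrix  # outgroup excluded
    divergence: DivergenceSummary
    gap: GapHistogram | None
    best_match: IdentificationReport
    tree_report: IdentificationReport
    tree: object
    verdicts: list


@dataclass
class RunResult:
    config: RunConfig
    regions: dict = field(default_factory=dict)  # region -> RegionResult
    wilcoxon: list = field(default_factory=list)  # (a, b, level, WilcoxonResult, n_units)
    ranking: list = field(default_factory=list)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    for h in list(log.handlers):
        if isinstance(h, logging.FileHandler):
            h.close()
            log.removeHandler(h)
    if not log.handlers:
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def evaluate_region(
    region: str,
    records,
    config: RunConfig,
) -> RegionResult:
    """All per-region computations for one labelled record set."""
    aln = RegionAlignment(region=region, records=list(records))
    outgroup = [s for s in aln.sample_ids if s in set(config.outgroup)]
    ingroup_ids = [s for s in aln.sample_ids if s not in set(config.outgroup)]
    in_aln = aln.subset(ingroup_ids) if outgroup else aln

    summary = summarize_region(in_aln.records, in_aln)
    dm_full = distance_matrix(aln, on_undefined=config.on_undefined)
    dm = dm_full.drop(outgroup) if outgroup else dm_full

    div = divergence_summary(dm, region=region)
    if div.avg_intra is None:
        log.warning("%s: no species with >= 2 individuals; intraspecific parameters undefined", region)
    try:
        gap = barcoding_gap(dm, bin_width=config.bin_width)
    except InsufficientDataError as exc:
        log.warning("%s: barcoding gap not computable (%s)", region, exc)
        gap = None

    verdicts = best_match_identify(dm_full, tie_tolerance=config.tie_tolerance, exclude=outgroup)
    skipped = len(dm) - len(verdicts)
    if skipped:
        log.info("%s: %d singleton-species queries excluded from best-match", region, skipped)
    bm_report = identification_rates(region=region, verdicts=verdicts)

    tree = bootstrap_supports(aln, replicates=config.replicates, seed=config.seed)
    tree_report = identification_rates(
        region=region, tree=tree, species_of=aln.species_of, outgroup=outgroup
    )
    return RegionResult(
        region=region,
        summary=summary,
        dm=dm,
        divergence=div,
        gap=gap,
        best_match=bm_report,
        tree_report=tree_report,
        tree=tree,
        verdicts=verdicts,
    )


def compare_regions(results: dict) -> list:
    """Rank regions by identification efficiency.

    Lexicographic over (tree species rate, best-match species rate,
    average interspecific distance), descending; ties broken by region
    name so the order is deterministic.  No composite score is used.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 evaluated regions to compare")
    rows = []
    for region, res in results.items():
        rows.append(
            {
                "region": region,
                "tree_species_rate": res.tree_report.species_rate,
                "best_match_species_rate": res.best_match.species_rate,
                "avg_inter": res.divergence.avg_inter.mean,
                "gap_overlap": res.gap.overlap if res.gap else None,
            }
        )
    rows.sort(
        key=lambda r: (
            -r["tree_species_rate"],
            -r["best_match_species_rate"],
            -r["avg_inter"],
            r["region"],
        )
    )
    return rows


# ---------------------------------------------------------------------------
# TSV emitters
# ---------------------------------------------------------------------------

def _summary_tsv(results) -> str:
    lines = ["region\tn_samples\tlength_min\tlength_max\tgc_min\tgc_max\tvariable_sites\tvariable_pct"]
    for res in results.values():
        s = res.summary
        lines.append(
            f"{s.region}\t{s.n_samples}\t{s.length_min}\t{s.length_max}"
            f"\t{s.gc_min:.1f}\t{s.gc_max:.1f}\t{s.variable_sites}\t{s.variable_pct:.2f}"
        )
    return "\n".join(lines) + "\n"


def _fmt_meansd(ms) -> str:
    return f"{ms.mean:.4f} ± {ms.sd:.4f}" if ms is not None else "NA"


def _divergence_tsv(results) -> str:
    params = [
        ("Interspecific distance", "avg_inter"),
        ("Theta prime", "theta_prime"),
        ("Minimum interspecific", "min_inter"),
        ("Intraspecific distance", "avg_intra"),
        ("Theta", "theta"),
        ("Coalescent depth", "coalescent_depth"),
    ]
    regions = list(results)
    lines = ["Parameter\t" + "\t".join(regions)]
    for label, attr in params:
        row = [label]
        for region in regions:
            row.append(_fmt_meansd(getattr(results[region].divergence, attr)))
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"


def _gap_tsv(gap: GapHistogram) -> str:
    lines = ["bin_low\tbin_high\tintra_count\tinter_count"]
    w = gap.bin_width
    for k in range(gap.n_bins):
        lines.append(f"{k * w:.2f}\t{(k + 1) * w:.2f}\t{gap.intra_counts[k]}\t{gap.inter_counts[k]}")
    lines.append(f"# overlap={gap.overlap} overlap_fraction={gap.overlap_fraction:.4f}")
    return "\n".join(lines) + "\n"


def _wilcoxon_tsv(rows) -> str:
    lines = ["region_a\tregion_b\tlevel\tW_plus\tW_minus\tn\tp_value\tverdict"]
    for a, b, level, w in rows:
        lines.append(
            f"{a}\t{b}\t{level}\t{w.w_plus:g}\t{w.w_minus:g}\t{w.n}\t{w.p_value:.3g}\t{w.verdict}"
        )
    return "\n".join(lines) + "\n"


def _identification_tsv(results) -> str:
    lines = [
        "region\tn_samples\tbest_match_species_rate\tbest_match_n_species"
        "\tbest_match_sample_rate\ttree_species_rate\ttree_n_species"
    ]
    for res in results.values():
        bm, tr = res.best_match, res.tree_report
        lines.append(
            f"{res.region}\t{bm.n_samples}\t{bm.species_rate:.2f}\t{bm.n_identified}/{bm.n_species}"
            f"\t{bm.sample_rate:.2f}\t{tr.species_rate:.2f}\t{tr.n_identified}/{tr.n_species}"
        )
    return "\n".join(lines) + "\n"


def _verdicts_tsv(verdicts) -> str:
    lines = ["sample_id\ttrue_species\tbest_hit_species\tbest_distance\tclassification"]
    for v in verdicts:
        hits = ";".join(sorted(v.best_hit_species))
        lines.append(f"{v.sample_id}\t{v.true_species}\t{hits}\t{v.best_distance:.6f}\t{v.classification}")
    return "\n".join(lines) + "\n"


def run_evaluation(config: RunConfig, records_by_region: dict | None = None) -> RunResult:
    """Run the full evaluation and write the report bundle.

    ``records_by_region`` may supply records directly (e.g. from the
    simulator); otherwise each region's FASTA in ``config.inputs`` is
    read.  Emits summary/divergence/identification/wilcoxon TSVs, per
    region a gap histogram TSV, a verdict TSV and a Newick tree with
    bootstrap supports, plus ``manifest.json`` and ``run.log``.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(config.outdir)
    result = RunResult(config=config)

    for region, path in config.inputs.items():
        if records_by_region is not None and region in records_by_region:
            records = records_by_region[region]
        else:
            records = read_labelled_fasta(path, delimiter=config.delimiter, region=region)
        if not records:
            raise ValueError(f"stage seq_io [{region}]: no records found")
        log.info("%s: %d records", region, len(records))
        try:
            result.regions[region] = evaluate_region(region, records, config)
        except (InsufficientSpeciesError, ValueError) as exc:
            raise RuntimeError(f"stage evaluate [{region}]: {exc}") from exc

    regions = list(result.regions)
    if len(regions) < 2:
        log.info("single region: Wilcoxon between-region stage skipped")
    else:
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                a, b = regions[i], regions[j]
                dm_a, dm_b = result.regions[a].dm, result.regions[b].dm
                for level in ("species-pair", "sample-pair"):
                    try:
                        va, vb, roster = pair_regions(dm_a, dm_b, level=level)
                    except ValueError as exc:
                        log.warning("wilcoxon %s vs %s (%s): %s", a, b, level, exc)
                        continue
                    w = wilcoxon_signed_rank(va, vb, alpha=config.alpha)
                    result.wilcoxon.append((a, b, level, w))
                    log.info(
                        "wilcoxon %s vs %s (%s): n=%d p=%.3g %s",
                        a, b, level, w.n, w.p_value, w.verdict,
                    )
        result.ranking = compare_regions(result.regions)

    out = config.outdir
    (out / "summary.tsv").write_text(_summary_tsv(result.regions))
    (out / "divergence.tsv").write_text(_divergence_tsv(result.regions))
    (out / "identification.tsv").write_text(_identification_tsv(result.regions))
    if result.wilcoxon:
        (out / "wilcoxon.tsv").write_text(_wilcoxon_tsv(result.wilcoxon))
    for region, res in result.regions.items():
        if res.gap is not None:
            (out / f"gap_{region}.tsv").write_text(_gap_tsv(res.gap))
        (out / f"verdicts_{region}.tsv").write_text(_verdicts_tsv(res.verdicts))
        write_newick(res.tree, out / f"tree_{region}.nwk")
    if result.ranking:
        lines = ["rank\tregion\ttree_species_rate\tbest_match_species_rate\tavg_inter\tgap_overlap"]
        for k, row in enumerate(result.ranking, 1):
            lines.append(
                f"{k}\t{row['region']}\t{row['tree_species_rate']:.2f}"
                f"\t{row['best_match_species_rate']:.2f}\t{row['avg_inter']:.4f}\t{row['gap_overlap']}"
            )
        (out / "ranking.tsv").write_text("\n".join(lines) + "\n")

    manifest = {
        "version": __version__,
        "inputs": {k: str(v) for k, v in config.inputs.items()},
        "outgroup": list(config.outgroup),
        "replicates": config.replicates,
        "seed": config.seed,
        "alpha": config.alpha,
        "bin_width": config.bin_width,
        "on_undefined": config.on_undefined,
        "tie_tolerance": config.tie_tolerance,
        "python": sys.version.split()[0],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return result
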