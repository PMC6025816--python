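"""Per-region sequence summaries: ungapped length range, GC range,
variable sites (count and percent of alignment columns).

Writes results/summary.tsv.
"""

from barcodegap.seq_io import summarize_region

from common import RESULTS, load_all


def main():
    lines = [
        "region\tn_samples\tlength_range_bp\tgc_range_pct\tvariable_sites\tvariable_pct"
    ]
    for region, aln in load_all().items():
        s = summarize_region(aln.records, aln)
        lines.append(
            f"{s.region}\t{s.n_samples}\t{s.length_min}-{s.length_max}"
            f"\t{s.gc_min:.1f}-{s.gc_max:.1f}\t{s.variable_sites}\t{s.variable_pct:.2f}"
        )
        print(lines[-1].replace("\t", "  "))
    out = RESULTS / "summary.tsv"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
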