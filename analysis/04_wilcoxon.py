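"""Between-region Wilcoxon signed-rank comparisons of divergence:
interspecific values paired at the species-pair level, intraspecific
values paired at the conspecific sample-pair level.

Writes results/wilcoxon.tsv.
"""

import itertools

from barcodegap.distances import distance_matrix
from barcodegap.divergence import pair_regions, wilcoxon_signed_rank
from barcodegap.pipeline import _wilcoxon_tsv

from common import RESULTS, load_all


def main():
    dms = {
        region: distance_matrix(aln, on_undefined="drop-pair")
        for region, aln in load_all().items()
    }
    rows = []
    for a, b in itertools.combinations(dms, 2):
        for level in ("species-pair", "sample-pair"):
            va, vb, roster = pair_regions(dms[a], dms[b], level=level)
            w = wilcoxon_signed_rank(va, vb)
            rows.append((a, b, level, w))
            print(
                f"{a} vs {b} [{level}]: W+={w.w_plus:g} W-={w.w_minus:g} "
                f"n={w.n} p={w.p_value:.3g} -> {w.verdict}"
            )
    out = RESULTS / "wilcoxon.tsv"
    out.write_text(_wilcoxon_tsv(rows))
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
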