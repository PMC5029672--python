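"""Build the weighted co-expression network and relate modules to traits.

Selects the most variable transcripts, picks a soft-threshold power,
computes topological overlap, detects and merges modules, and correlates
each module eigengene with the NC/PC/MC group indicators.  Writes
module_labels.tsv, module_eigengenes.tsv and module_trait_cor.tsv under
results/ and reports planted-module recovery.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from lncscape import expression as ex
from lncscape import network as net

from _data import RESULTS, load

N_VARIABLE = 600  # most variable transcripts used for network construction


def main() -> None:
    ann, counts, samples, truth = load()
    log_expr = ex.log_rpkm(ex.rpkm(counts, ann))
    ms = net.build_network(log_expr, samples, n_variable=N_VARIABLE)
    ms.labels.rename("module").to_frame().to_csv(RESULTS / "module_labels.tsv", sep="\t")
    ms.eigengenes.to_csv(RESULTS / "module_eigengenes.tsv", sep="\t")
    ms.trait_correlation.to_csv(RESULTS / "module_trait_cor.tsv", sep="\t")

    sizes = {m: (ms.labels == m).sum() for m in ms.module_ids}
    print(f"power {ms.power}; {len(ms.module_ids)} modules after merging: sizes {sizes}")

    planted = {g: m for g, m in truth["module_labels"].items() if g in ms.labels.index}
    print(f"{len(planted)}/{len(truth['module_labels'])} planted module members "
          f"survived the variance filter")
    # the DE genes legitimately form their own trait-correlated modules, so
    # score label agreement on the planted members only
    members = list(planted)
    ari = adjusted_rand_score(pd.Series(planted)[members], ms.labels[members])
    print(f"module-label ARI on planted members: {ari:.3f}")

    trait_of = {m: t for m, t in truth["module_traits"].items()}
    for trait in ("NC", "PC", "MC"):
        rows = ms.trait_correlation.xs(trait, level="trait")
        best = rows["r"].idxmax()
        planted_trait = {g for g, m in planted.items() if trait_of.get(str(m)) == trait}
        in_best = len(set(ms.labels.index[ms.labels == best]) & planted_trait)
        msg = (f" | contains {in_best}/{len(planted_trait)} planted {trait}-module members"
               if planted_trait else "")
        print(f"trait {trait}: best module {best} "
              f"(r = {rows.loc[best, 'r']:.3f}, p = {rows.loc[best, 'p']:.2g}){msg}")


if __name__ == "__main__":
    main()
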