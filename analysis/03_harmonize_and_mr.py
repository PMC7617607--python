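"""Harmonize proxies against each outcome GWAS and run random-effects IVW.

Writes results/mr_estimates.tsv: one row per protein x source x outcome with
the odds ratio, confidence interval, heterogeneity, and exposure scale.
"""

import pandas as pd
from _common import RESULTS, get_bundle

from coagmr.harmonize import harmonize_sets, retained
from coagmr.mr import ivw, rescale_per_doubling
from coagmr.proxies import SelectionParams, select_proxies


def main() -> None:
    bundle = get_bundle()
    params = SelectionParams()
    liability = bundle.trait_sets["vte"]
    outcomes = {
        tid: ss
        for tid, ss in sorted(bundle.trait_sets.items())
        if ss.trait_type == "binary"
    }

    rows = []
    for protein_id, meta in bundle.proteins.items():
        region = bundle.regions[meta["region"]]
        ld = bundle.ld[meta["region"]]
        sources = {
            f"pqtl_{c}": bundle.trait_sets[f"{protein_id}_{c}"]
            for c in meta["cohorts"]
        }
        sources["liability"] = liability
        for ps in select_proxies(
            protein_id, sources, liability, bundle.trait_sets["stroke"],
            region, ld, params,
        ):
            if ps.no_proxy:
                continue
            for out_id, out_ss in outcomes.items():
                if ps.source == "liability" and out_id == "vte":
                    continue
                pairs = retained(
                    harmonize_sets(ps.exposure.records, list(out_ss.records))
                )
                if not pairs:
                    continue
                est = ivw(pairs, exposure_id=protein_id, outcome_id=out_id)
                if ps.source == "liability":
                    # theta is already per unit VTE log-odds; re-expressing it
                    # per doubling of liability odds multiplies by ln 2
                    est = rescale_per_doubling(est, 1.0)
                row = est.summary_row()
                row.update(protein=protein_id, source=ps.source)
                rows.append(row)

    RESULTS.mkdir(exist_ok=True)
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "mr_estimates.tsv", sep="\t", index=False)
    stroke = df[df.outcome == "stroke"]
    print(f"{len(df)} MR estimates -> {RESULTS / 'mr_estimates.tsv'}")
    print(stroke[["protein", "source", "or", "pval"]].to_string(index=False))


if __name__ == "__main__":
    main()
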