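"""Select cis instruments for every protein from every source data set.

Writes results/proxies.tsv (one row per retained proxy) and
results/proxy_audit.tsv (one row per filter step per protein x source).
"""

import pandas as pd
from _common import RESULTS, get_bundle

from coagmr.proxies import SelectionParams, select_proxies


def main() -> None:
    bundle = get_bundle()
    params = SelectionParams()
    liability = bundle.trait_sets["vte"]
    primary = bundle.trait_sets["stroke"]

    proxy_rows, audit_rows = [], []
    for protein_id, meta in bundle.proteins.items():
        region = bundle.regions[meta["region"]]
        ld = bundle.ld[meta["region"]]
        sources = {
            f"pqtl_{c}": bundle.trait_sets[f"{protein_id}_{c}"]
            for c in meta["cohorts"]
        }
        sources["liability"] = liability
        for ps in select_proxies(
            protein_id, sources, liability, primary, region, ld, params
        ):
            for rec in ps.exposure.records:
                proxy_rows.append(
                    {
                        "protein": protein_id,
                        "source": ps.source,
                        "variant_id": rec.variant_id,
                        "pos": rec.pos,
                        "eaf": rec.eaf,
                        "beta": rec.beta,
                        "se": rec.se,
                        "pval": rec.pval,
                    }
                )
            for step in ps.audit_trail():
                audit_rows.append(
                    {"protein": protein_id, "source": ps.source, **step}
                )

    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(proxy_rows).to_csv(RESULTS / "proxies.tsv", sep="\t", index=False)
    pd.DataFrame(audit_rows).to_csv(
        RESULTS / "proxy_audit.tsv", sep="\t", index=False
    )
    n_proteins = len({r["protein"] for r in proxy_rows})
    print(
        f"{len(proxy_rows)} proxies across {n_proteins} proteins "
        f"-> {RESULTS / 'proxies.tsv'}"
    )


if __name__ == "__main__":
    main()
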