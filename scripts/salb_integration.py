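"""Integration checks against released genome-scale model files.

These analyses need the published SBML releases of the *S. albus* model
(and optionally its *S. coelicolor* template), which are not bundled here;
download them separately and point this script at the local files.  For
each model it reports:

* reaction / metabolite / gene counts after parsing,
* single-gene-deletion essential-gene count on a user-supplied minimal
  medium,
* the paralogue fraction (reactions whose GPR offers >= 2 alternative
  gene sets),
* optionally, the GAEC fitted so growth matches a target rate at a fixed
  NGAM.

The medium file is a YAML mapping of exchange-reaction id to maximum
uptake rate (mmol/gDW/h), e.g.::

    EX_glc__D_e: 1.0
    EX_nh4_e: 1000
    EX_pi_e: 1000
    EX_so4_e: 1000
    EX_o2_e: 1000
    EX_h2o_e: 1000
    EX_h_e: 1000

Usage:
    python scripts/salb_integration.py MODEL.xml --medium medium.yaml \
        [--maintenance ATPM --target-growth 0.04 --ngam 6.86]
"""

import argparse
from pathlib import Path

import yaml

from gemsmith.biomass import calibrate_energetics
from gemsmith.essentiality import (
    classify_essential,
    paralogue_fraction,
    single_gene_deletion,
)
from gemsmith.fba import solve_fba
from gemsmith.io import read_model


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("model", type=Path)
    parser.add_argument("--medium", type=Path, required=True)
    parser.add_argument("--objective", default=None)
    parser.add_argument("--threshold", type=float, default=1 / 3)
    parser.add_argument("--maintenance", default=None,
                        help="maintenance reaction id; enables calibration")
    parser.add_argument("--target-growth", type=float, default=0.04)
    parser.add_argument("--ngam", type=float, default=6.86)
    args = parser.parse_args()

    model = read_model(args.model)
    s = model.summary()
    print(f"parsed {args.model.name}: {s['reactions']} reactions, "
          f"{s['metabolites']} metabolites, {s['genes']} genes")

    medium = {
        str(k): float(v)
        for k, v in yaml.safe_load(args.medium.read_text()).items()
    }
    sol = solve_fba(model, args.objective, medium=medium)
    print(f"growth on supplied medium: {sol.status}, "
          f"objective {sol.objective_value}")
    if not sol.optimal or sol.objective_value <= 0:
        raise SystemExit("model does not grow on the supplied medium; "
                         "essentiality and calibration skipped")

    results = single_gene_deletion(model, medium)
    report = classify_essential(results, args.threshold)
    print(f"essential genes (ratio <= {args.threshold:.4g}): "
          f"{len(report.essential_genes)} of {len(results)}")

    frac = paralogue_fraction(model)
    print(f"paralogue fraction: {100 * frac:.1f}%")

    if args.maintenance:
        params = calibrate_energetics(
            model, args.target_growth, medium, [args.ngam],
            maintenance_rxn=args.maintenance, objective=args.objective,
        )
        print(f"fitted GAEC at NGAM {params.ngam}: {params.gaec:.4g} mmol/gDW")


if __name__ == "__main__":
    main()
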