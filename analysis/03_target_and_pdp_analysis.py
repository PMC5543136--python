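#!/usr/bin/env python
"""Target analysis of the paired pump-probe / pump-dump-probe data.

Jointly fits both matrices with the branched kinetic scheme (shared
kinetics and SADS, dataset-specific dump transfer fractions) under the
equal-bleach spectral constraint, then reports the microscopic rates,
the dump efficiencies, the photoisomerization quantum yield with its
propagated uncertainty, and the dump-delay dependence of the product
loss.  Results go to results/target/.
"""

from pathlib import Path

import numpy as np

from takinetics import (
    calibrate_dump_fraction,
    dump_readout,
    fit_target,
    read_matrix,
    read_scheme,
)
from takinetics.io import write_fit_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main():
    data = ROOT / "data"
    for f in ("pdp_pair_pp.tsv", "pdp_pair_pdp.tsv", "target_scheme_ph8.txt"):
        if not (data / f).exists():
            raise SystemExit(f"{data / f} missing; run 01_simulate_datasets.py")
    scheme_file = read_scheme(data / "target_scheme_ph8.txt")
    pp = read_matrix(data / "pdp_pair_pp.tsv")
    pdp = read_matrix(data / "pdp_pair_pdp.tsv")
    pdp.meta["dump_events"] = scheme_file.dump_events
    scheme = scheme_file.with_dump_events([])
    from takinetics import IRFModel

    irf = IRFModel.from_fwhm(0.150)

    init = scheme.with_rates(
        {("GSI", "GS"): 0.5, ("ES2", "ES3"): 0.2, ("ES2", "GS"): 0.3}
    )
    fit = fit_target(
        [pp, pdp], init, irfs=irf,
        free_rates=[("GSI", "GS"), ("ES2", "ES3"), ("ES2", "GS")],
        free_dump=[("ES1", "GSI"), ("ES2", "GSI")],
        bleach_window=(430.0, 465.0), bleach_weight=1.0,
        n_starts=4, seed=0,
    )
    print("== joint PP + PDP target fit (equal-bleach constrained)")
    print(fit.summary())
    y, err = fit.extra["yields"]["K1"]
    print(f"   photoisomerization quantum yield: {100 * y:.1f} +/- "
          f"{100 * err:.2f}% (generating value 30%)")
    print(f"   GSI decay rate: {fit.params['k:GSI->GS']:.3f} /ps "
          "(generating value 1.0 /ps)")

    print("\n== dump-delay dependence (11% excited-state removal)")
    print("   t_dump (ps)   product loss")
    for td in (0.3, 0.6, 1.0, 2.0, 5.0):
        ev = calibrate_dump_fraction(scheme, irf, td, 0.11,
                                     sources=("ES1", "ES2"))
        ro = dump_readout(scheme, irf, ev)
        print(f"   {td:8.1f}   {100 * ro.product_loss_fraction:8.2f}%")
    print("   -> early dumps matter most: the photoproduct forms from the "
          "fastest excited-state component")

    out = write_fit_report(fit, ROOT / "target", name="pdp_joint",
                           extra_meta={"quantum_yield": y,
                                       "quantum_yield_stderr": err})
    print(f"\nreport written to {out.parent}")


if __name__ == "__main__":
    main()
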