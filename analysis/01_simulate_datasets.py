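#!/usr/bin/env python
"""Generate the synthetic study datasets with known ground truth.

Writes, under results/data/:
  * pH 8 and pH 10 femtosecond pump-probe matrices (six / seven
    sequential components, 150 fs IRF, 1% peak noise, 465-495 nm
    scatter mask),
  * a paired pump-probe / pump-dump-probe set from the branched target
    scheme with a 300 fs dump into the ground-state intermediate,
  * a microsecond-to-second flash-photolysis matrix from the three-stage
    photocycle chain,
plus the scheme configuration files and a JSON manifest of the
generating parameters.
"""

import json
from pathlib import Path

import numpy as np

from takinetics import (
    DumpEvent,
    NoiseModel,
    c1c2_presets,
    default_wavelength_axis,
    linlog_time_axis,
    simulate_dataset,
    simulate_pdp_matrix,
    write_matrix,
    write_scheme,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2024


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": SEED, "noise_fraction_of_peak": 0.01, "files": {}}

    for ph in (8, 10):
        p = c1c2_presets(ph)
        ds = simulate_dataset(
            p.sequential_scheme, p.sequential_spectra, p.irf,
            linlog_time_axis(), default_wavelength_axis(),
            noise=NoiseModel(0.01, seed=SEED + ph),
        )
        name = f"pp_ph{ph}.tsv"
        write_matrix(ds, OUT / name, title=f"synthetic pump-probe pH {ph}")
        manifest["files"][name] = {
            "kind": "pump-probe",
            "sequential_lifetimes_ps": [
                t if np.isfinite(t) else "inf" for t in p.sequential_lifetimes
            ],
            "irf_fwhm_ps": p.irf.fwhm,
        }
        print(f"pH {ph}: {ds.shape[0]} delays x {ds.shape[1]} wavelengths, "
              f"{len(p.sequential_lifetimes)} components -> {name}")

    p8 = c1c2_presets(8)
    ev = DumpEvent(0.3, [("ES1", "GSI", 0.1), ("ES2", "GSI", 0.1)])
    pp, pdp = simulate_pdp_matrix(
        p8.target_scheme, p8.target_spectra, p8.irf, ev,
        linlog_time_axis(-1.0, 2.0, 100.0, 250, lin_step=0.02),
        default_wavelength_axis(), noise=NoiseModel(0.01, seed=SEED + 20),
    )
    write_matrix(pp, OUT / "pdp_pair_pp.tsv", title="PP twin of the PDP run")
    write_matrix(pdp, OUT / "pdp_pair_pdp.tsv", title="PDP with 300 fs dump")
    write_scheme(p8.target_scheme.with_dump_events([ev]),
                 OUT / "target_scheme_ph8.txt")
    manifest["files"]["pdp_pair_pdp.tsv"] = {
        "kind": "pump-dump-probe",
        "dump_time_ps": ev.time,
        "dump_transfers": [list(t) for t in ev.transfers],
    }
    print(f"PDP pair: {pp.shape[0]} delays, dump at {ev.time} ps "
          "(fractions 0.1 from ES1 and ES2)")

    flash = simulate_dataset(
        p8.photocycle_scheme, p8.photocycle_spectra, None,
        np.geomspace(1e6, 1e13, 120), np.linspace(360.0, 660.0, 61),
        noise=NoiseModel(0.01, seed=SEED + 30), mask_windows=(),
    )
    write_matrix(flash, OUT / "flash_ph8.tsv", time_unit="us",
                 title="synthetic flash photolysis pH 8")
    write_scheme(p8.photocycle_scheme, OUT / "photocycle_scheme_ph8.txt")
    manifest["files"]["flash_ph8.tsv"] = {
        "kind": "flash-photolysis",
        "lifetimes_ps": list(p8.photocycle_lifetimes),
    }
    print(f"flash photolysis: {flash.shape[0]} delays (1 us .. 10 s)")

    (OUT / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"\nall datasets written to {OUT}")


if __name__ == "__main__":
    main()
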