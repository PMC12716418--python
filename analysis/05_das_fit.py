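#!/usr/bin/env python
"""Simulate a four-component transient-absorption experiment and recover its
decay-associated spectra by global fitting.

The synthetic cube uses the four-component decay model (0.16 ps relaxation /
Chl c feeding, 2.8 ps inner-antenna-to-core transfer, 62 ps bulk
antenna-to-core decay, 5 ns uncoupled-chromophore tail) with a 70-fs IRF and
1% noise.  The fit shares lifetimes across wavelengths (variable projection)
and writes the recovered DAS, lifetimes, and component labels.
"""

import json
from pathlib import Path

from eetscape import fit_global, report_components
from eetscape.synthetic import TASimSpec, make_ta_cube

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    spec = TASimSpec(seed=SEED)
    cube = make_ta_cube(spec)
    cube.to_csv(SCRATCH / "ta_cube.csv")  # raw cube is bulky; regenerable

    result = fit_global(cube, n_components=4)
    result.to_frame().to_csv(OUT / "das_spectra.csv")
    report = report_components(result)
    report.to_csv(OUT / "das_components.csv", index=False)
    (OUT / "das_fit.json").write_text(
        json.dumps(
            {
                "lifetimes_ps": result.lifetimes.tolist(),
                "true_lifetimes_ps": [c.lifetime for c in spec.components],
                "residual_norm": result.residual_norm,
                "irf_fwhm_ps": result.irf_fwhm,
                "converged": result.success,
            },
            indent=2,
        )
        + "\n"
    )

    print("recovered lifetimes (ps):",
          [f"{tau:.3g}" for tau in result.lifetimes])
    print("generator lifetimes (ps):", [c.lifetime for c in spec.components])
    print(report.to_string(index=False))
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
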