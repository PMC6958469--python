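#!/usr/bin/env python
"""Generate the four synthetic datasets the downstream analyses consume.

Emulates the study design end to end: fixed-ratio viability plates for both
a Bliss-null and a synergistic interaction, the ten-arm xenograft efficacy
study (with programmed synergy on the combination arms), targeted and
isotype biodistribution, and the hematology time courses. Writes CSVs plus
``*.truth.json`` ground-truth sidecars under results/data/.
"""

import dataclasses
import json
from pathlib import Path

from radiosynergy.experiments import psi_for_combination_tc
from radiosynergy.pipeline import _jsonable
from radiosynergy.simulate import (
    BiodistSimSpec,
    HemeSimSpec,
    PlateSimSpec,
    XenoSimSpec,
    gen_biodistribution,
    gen_hematology,
    gen_viability_plates,
    gen_xenograft_study,
)

SEED = 20190155
OUT = Path("results/data")


def emit(df, truth, name, extra=None):
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / f"{name}.csv", index=False)
    (OUT / f"{name}.truth.json").write_text(json.dumps(_jsonable(truth), indent=2) + "\n")
    if extra is not None:
        extra.to_csv(OUT / f"{name}.censoring.csv", index=False)
    print(f"  {name}.csv: {len(df)} rows")


def main():
    print("simulating viability plates (Bliss-null gamma=1 and synergy gamma=1.6)")
    for gamma, name in ((1.0, "plates_null"), (1.6, "plates_synergy")):
        df, truth = gen_viability_plates(PlateSimSpec(gamma=gamma, seed=SEED))
        emit(df, truth, name)

    print("simulating the ten-arm xenograft study (programmed synergy on combinations)")
    psi = psi_for_combination_tc(0.05)
    base = XenoSimSpec(seed=SEED)
    arms = tuple(
        dataclasses.replace(a, psi=psi) if (a.ttc_kbq_kg > 0 and a.olaparib_mg_kg > 0) else a
        for a in base.arms
    )
    df, censoring, truth = gen_xenograft_study(dataclasses.replace(base, arms=arms))
    emit(df, truth, "tumor_volumes", extra=censoring)
    print(f"  ({len(censoring)} humane-endpoint censoring events)")

    print("simulating biodistribution (targeted + isotype)")
    for mode in ("targeted", "isotype"):
        df, truth = gen_biodistribution(BiodistSimSpec(mode=mode, seed=SEED))
        emit(df, truth, f"biodistribution_{mode}")

    print("simulating hematology")
    df, truth = gen_hematology(HemeSimSpec(seed=SEED))
    emit(df, truth, "hematology")


if __name__ == "__main__":
    main()
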