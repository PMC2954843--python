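#!/usr/bin/env python
"""Generate the synthetic study that the downstream analyses consume.

Builds a two-cohort case/control array study with known ground truth:
a primary cohort of 60 cases + 60 controls and an external control
cohort of 60, differentiated at F_ST = 0.005; a 2-Mb homozygous tract
enriched in cases (15 case / 5 control carriers); one duplicate and two
parent-offspring pairs hidden in the primary cohort; a CNV call set
with excess large calls in cases; and age/sex covariates.  Everything
is written as plain text under results/simdata/, with ground-truth
sidecars so later steps can score themselves against the truth.
"""

from pathlib import Path

import pandas as pd

from popscan import attach_metadata, write_plink_text
from popscan.cnv import write_rawcnv
from popscan.simulate import (
    AgeSexModel, ChromLayout, CNVPlan, RelatednessPlan, SimulationConfig,
    plant_roh, simulate_cnv_calls, simulate_phenotypes, simulate_relatives,
    simulate_structured_cohort,
)

SEED = 20100921
OUT = Path("results/simdata")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(
        seed=SEED, n_pop1=120, n_pop2=60,
        layout=ChromLayout([("1", 2500), ("2", 2500)]),
        fst=0.005, missing_rate=0.01)
    ds = simulate_structured_cohort(cfg)

    # primary cohort: first 60 are cases, next 60 controls; pop2 external
    status = {}
    for i, s in enumerate(ds.samples):
        if s.cohort == "pop1":
            status[s.id] = "case" if i < 60 else "control"
        else:
            status[s.id] = "control"

    # enriched 2-Mb tract on chromosome 1 (cases 15/60, controls 5/60)
    cases = [s for s in ds.sample_ids if status[s] == "case"]
    p1_ctrl = [s for s in ds.sample_ids[:120] if status[s] == "control"]
    tract = ("1", 4_000_000, 6_000_000)
    carriers = cases[:15] + p1_ctrl[:5]
    ds = plant_roh(ds, tract, carriers, het_flank=2)
    pd.DataFrame({"sample": carriers, "chrom": tract[0],
                  "start": tract[1], "end": tract[2],
                  "status": [status[c] for c in carriers]}).to_csv(
        OUT / "truth_roh_tract.tsv", sep="\t", index=False)

    # hidden relatives appended to the primary cohort
    ds, rel_truth = simulate_relatives(ds, RelatednessPlan(1, 2), SEED + 1)
    rel_truth.to_csv(OUT / "truth_relatives.tsv", sep="\t", index=False)
    for rid in rel_truth["new_id"]:
        status[rid] = "control"

    pheno = simulate_phenotypes(ds.sample_ids, AgeSexModel(), SEED + 2)
    meta = pd.DataFrame({
        "id": ds.sample_ids,
        "cohort": [s.cohort for s in ds.samples],
        "status": [status[s] for s in ds.sample_ids],
        "sex": pheno["sex"], "age": pheno["age"]})
    attach_metadata(ds, meta)
    write_plink_text(ds, OUT / "cohort.ped", OUT / "cohort.map")
    meta.to_csv(OUT / "meta.tsv", sep="\t", index=False)

    # CNV call set over the primary cohort
    labels = {s: status[s] for s in ds.sample_ids
              if not s.startswith("pop2")}
    calls, large = simulate_cnv_calls(CNVPlan(), labels, SEED + 3)
    write_rawcnv(calls, OUT / "cohort.rawcnv")
    pd.DataFrame({"sample": sorted(large)}).to_csv(
        OUT / "truth_large_cnv_carriers.tsv", sep="\t", index=False)

    print(f"simulated {ds.n_samples} samples x {ds.n_markers} markers "
          f"({cfg.fst=} between cohorts)")
    print(f"planted ROH tract {tract} in {len(carriers)} carriers "
          "(15 cases / 5 primary controls)")
    print(f"hidden relatives: {len(rel_truth)} pairs; "
          f"CNV calls: {len(calls)} ({len(large)} large-call carriers)")
    print(f"wrote inputs + ground-truth sidecars to {OUT}/")


if __name__ == "__main__":
    main()
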