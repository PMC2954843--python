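#!/usr/bin/env python
"""QC-filter the simulated cohort and remove hidden relatives.

Applies the two-pass QC (marker missingness, individual missingness,
MAF), estimates pi-hat for every sample pair, compares the flagged
pairs against the planted ground truth, and writes the pruned sample
list used by all later steps.
"""

from pathlib import Path

import pandas as pd

from popscan import (
    attach_metadata, estimate_pihat, prune_related, qc_filter,
    read_metadata, read_plink_text,
)

SIM = Path("results/simdata")
OUT = Path("results/qc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = read_plink_text(SIM / "cohort.ped", SIM / "cohort.map")
    attach_metadata(ds, read_metadata(SIM / "meta.tsv"))

    filtered, report = qc_filter(ds)
    print(f"QC: {report.summary()}")
    mk, sm = report.to_frames()
    mk.to_csv(OUT / "dropped_markers.tsv", sep="\t", index=False)
    sm.to_csv(OUT / "dropped_samples.tsv", sep="\t", index=False)

    est = estimate_pihat(filtered)
    flagged = [e for e in est if e.pihat > 0.25]
    kept = prune_related(est, sample_ids=filtered.sample_ids)
    pd.DataFrame([vars(e) for e in flagged]).to_csv(
        OUT / "related_pairs.tsv", sep="\t", index=False)
    pd.Series(kept, name="id").to_csv(OUT / "kept_samples.tsv",
                                      sep="\t", index=False)

    truth = pd.read_csv(SIM / "truth_relatives.tsv", sep="\t")
    flagged_pairs = {frozenset((e.sample_i, e.sample_j)) for e in flagged}
    truth_pairs = {frozenset((r.donor, r.new_id))
                   for r in truth.itertuples()}
    print(f"relatedness: {len(flagged)} pairs with pi-hat > 0.25; "
          f"{len(flagged_pairs & truth_pairs)}/{len(truth_pairs)} "
          "planted pairs recovered")
    removed = set(filtered.sample_ids) - set(kept)
    print(f"pruning removed {sorted(removed)} "
          f"(planted: {sorted(truth['new_id'])})")


if __name__ == "__main__":
    main()
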