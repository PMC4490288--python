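#!/usr/bin/env python
"""Generate the two study-style synthetic cohorts used by the analysis.

Writes a discovery-style twin cohort (212 subjects, 106 pairs, exclusion
flags placed so the standard filter leaves 195 subjects) and a
replication-style singleton cohort (254 subjects, 91/81/82 diagnosis split,
one planted protein -> left-entorhinal-volume effect restricted to female
controls) under results/cohorts/.

A 200-analyte panel is used throughout the drivers to keep them quick; the
full-width 1129-analyte panel is exercised by the test suite and the
acceptance script.
"""

from pathlib import Path

from twinprot import io, make_anm_fixture, make_paper_fixture

OUT = Path("results/cohorts")
N_ANALYTES = 200
SEED = 20150616

PLANTED = {
    "analyte": "A0003",
    "region": "le_volume",
    "beta": -0.6,
    "stratum": "female-controls",
}


def main():
    for name, (roster, proteins, phenotypes) in {
        "discovery": make_paper_fixture(seed=SEED, n_analytes=N_ANALYTES),
        "replication": make_anm_fixture(
            seed=SEED, n_analytes=N_ANALYTES, planted=PLANTED
        ),
    }.items():
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        io.write_roster(roster, d / "roster.tsv")
        io.write_proteins(proteins, d / "proteins.tsv")
        io.write_phenotypes(phenotypes, d / "phenotypes.tsv")
        print(
            f"{name}: {len(roster)} subjects x {proteins.shape[1]} analytes -> {d}"
        )
    print(
        "replication cohort carries a planted effect: "
        f"{PLANTED['analyte']} -> {PLANTED['region']} "
        f"(beta={PLANTED['beta']}) in {PLANTED['stratum']} only"
    )


if __name__ == "__main__":
    main()
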