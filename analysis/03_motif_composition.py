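#!/usr/bin/env python
"""Core-promoter element composition, combinations and co-occurrence.

Scans the preset cohorts for the seven element classes, tabulates per-class
frequencies and GC content, counts collapsed-class combinations
(TATA-class, BREu-class, INR, DPE) in the TFIIB- versus NC2-dominated
cohorts, and reports pairwise co-occurrence on the dedicated reference
cohorts.  Writes tables under results/motifs/.
"""

from pathlib import Path

import pandas as pd

from coreprom import cooccur, motifscan
from coreprom.presets import load_preset
from coreprom.synthcohort import generate_cohort

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results" / "motifs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    anns = {}
    for name in ("top100", "high_tfiib", "low_tfiib",
                 "tfiib_dominated", "nc2_dominated"):
        cohort = generate_cohort(load_preset(name, seed=SEED))
        anns[name] = motifscan.scan_cohort(cohort.promoters)
        freq = motifscan.motif_frequency(anns[name])
        freq.to_csv(OUT / f"frequency_{name}.tsv", sep="\t", float_format="%.2f")
        gc = 100 * motifscan.gc_content(cohort.promoters)
        print(f"{name}: TATA {freq.loc['TATA', 'percent']:.1f}%, "
              f"TATA-like {freq.loc['TATA_like', 'percent']:.1f}%, "
              f"INR {freq.loc['INR', 'percent']:.1f}%, GC {gc:.0f}%")
        motifscan.nucleotide_frequency_matrix(cohort.promoters).to_csv(
            OUT / f"base_frequency_{name}.tsv", sep="\t", float_format="%.4f")

    for name in ("tfiib_dominated", "nc2_dominated"):
        rep = cooccur.combination_counts(anns[name])
        rep.histogram.rename_axis("combination_size").to_csv(
            OUT / f"combinations_{name}.tsv", sep="\t")
        print(f"{name}: >=1 motif {rep.count_at_least(1)}%, "
              f"two motifs {rep.count_exactly(2)}%, "
              f"three motifs {rep.count_exactly(3)}% (collapsed classes)")
        cooccur.cooccur_matrix(anns[name]).to_csv(
            OUT / f"cooccur_matrix_{name}.tsv", sep="\t")

    inr = motifscan.scan_cohort(
        generate_cohort(load_preset("cooccur_inr", seed=SEED)).promoters)
    dpe = motifscan.scan_cohort(
        generate_cohort(load_preset("cooccur_dpe", seed=SEED)).promoters)
    rows = [
        ("INR", "TATA_like", cooccur.cooccur_fraction(inr, "INR", "TATA_like")),
        ("INR", "TATA", cooccur.cooccur_fraction(inr, "INR", "TATA")),
        ("DPE", "TATA_like", cooccur.cooccur_fraction(dpe, "DPE", "TATA_like")),
        ("DPE", "TATA", cooccur.cooccur_fraction(dpe, "DPE", "TATA")),
    ]
    tab = pd.DataFrame(rows, columns=["reference", "second", "percent"])
    tab.to_csv(OUT / "cooccurrence_fractions.tsv", sep="\t", index=False)
    for ref, sec, pct in rows:
        print(f"co-occurrence: {pct:.0f}% of {ref} promoters also carry {sec}")


if __name__ == "__main__":
    main()
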