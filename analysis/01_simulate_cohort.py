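"""Simulate the study cohort: a phased SNP panel with one planted sweep,
plus a fabricated gene annotation with one enriched term.

Writes results/sim/: haplotypes.txt + snp_map.tsv (the panel), genes.bed,
term_assoc.tsv + term_desc.tsv, and truth.json recording the planted
sweep tract/carriers and the enriched term.
"""

import argparse
import json
from pathlib import Path

from ehhscan import io, simulate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/sim")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cfg = simulate.SimulationConfig(seed=args.seed)
    panel = simulate.simulate_neutral_panel(cfg)
    pos = panel.snps["pos_bp"].to_numpy()
    sweep_pos = int(pos[len(pos) // 2])
    panel, truth = simulate.plant_sweep(panel, sweep_pos, carrier_fraction=0.4,
                                        tract_half_length_cm=1.0,
                                        seed=args.seed + 1000)
    io.write_haplotype_table(panel, out / "haplotypes.txt", out / "snp_map.tsv")

    chrom_len = int(pos[-1] + 1)
    genes, terms, desc, ann_truth = simulate.simulate_annotation(
        chrom_len, n_genes=800, n_terms=25, mean_genes_per_term=60,
        enriched_term_spec={"term_id": "T007",
                            "target_intervals_bp": [truth.sweep_tract_bp],
                            "multiplier": 8.0},
        seed=args.seed + 2000)
    genes[["chrom", "start_bp", "end_bp", "gene_id"]].to_csv(
        out / "genes.bed", sep="\t", header=False, index=False)
    with open(out / "term_assoc.tsv", "w") as fh:
        for term, members in sorted(terms.items()):
            for g in sorted(members):
                fh.write(f"{g}\t{term}\n")
    with open(out / "term_desc.tsv", "w") as fh:
        for term, d in sorted(desc.items()):
            fh.write(f"{term}\t{d}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump({"sweep_tract_bp": truth.sweep_tract_bp,
                   "sweep_position_bp": truth.sweep_position_bp,
                   "n_sweep_carriers": len(truth.sweep_carriers),
                   "enriched_term": "T007",
                   "chrom_length_bp": chrom_len,
                   "seed": args.seed}, fh, indent=1)

    print(f"panel: {panel.n_copies} copies x {panel.n_snps} SNPs, "
          f"chromosome {chrom_len/1e6:.1f} Mb")
    print(f"planted sweep: tract {truth.sweep_tract_bp} "
          f"({len(truth.sweep_carriers)} carrier copies, 40%)")
    print(f"annotation: {len(genes)} genes, {len(terms)} terms "
          f"(T007 enriched x8 inside the tract)")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
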