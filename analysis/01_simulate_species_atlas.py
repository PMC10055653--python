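"""Simulate the cross-species study inputs: ten synthetic species whose
planted pause-motif usage and pausing index rise together, written to
disk as FASTA + BED6 + stranded bedGraph pairs with a truth table, plus
the pipeline config that the downstream atlas run consumes.

Run from the repository root:  python analysis/01_simulate_species_atlas.py
"""

from pathlib import Path

import numpy as np
import yaml

from pauseatlas import synthetic_data as sd

OUT = Path("results/atlas_data")
N_SPECIES = 10
N_GENES = 80
READS_PER_GENE = 2000
MOTIF = "CGCCGCC"
SEED = 2026


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    fractions = np.linspace(0.0, 1.0, N_SPECIES)
    planted_pi = 2.0 * 10.0 ** (1.5 * fractions)
    species_cfg = {}
    for i in range(N_SPECIES):
        name = f"species_{i:02d}"
        genome, genes, truths = sd.generate_genome_with_genes(
            N_GENES, gene_length=2000, seed=SEED + 7 * i,
            pausing_index=float(planted_pi[i]), motif=MOTIF,
            motif_fraction=float(fractions[i]),
        )
        five, three = sd.simulate_proseq_tracks(
            genes, truths, total_reads=N_GENES * READS_PER_GENE,
            seed=SEED + 7 * i + 1,
        )
        paths = sd.emit_species_dataset(OUT / name, genome, genes, truths, five, three)
        species_cfg[name] = {
            "annotation": str(paths["genes"]),
            "genome": str(paths["genome"]),
            "five_prime": {"plus": str(paths["fp_plus"]), "minus": str(paths["fp_minus"])},
            "three_prime": {"plus": str(paths["tp_plus"]), "minus": str(paths["tp_minus"])},
        }
        print(f"{name}: planted motif fraction {fractions[i]:.2f}, "
              f"planted PI {planted_pi[i]:.1f}")
    cfg = {"seed": SEED, "outdir": "results/atlas_out", "species": species_cfg}
    cfg_path = OUT / "atlas.yaml"
    cfg_path.write_text(yaml.safe_dump(cfg))
    print(f"\nwrote {N_SPECIES} species datasets and config -> {cfg_path}")


if __name__ == "__main__":
    main()
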