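"""Distinguish incomplete lineage sorting from introgression on simulated loci.

Simulates triplet gene trees under the multispecies coalescent twice — once
with pure ILS and once with a 30% introgression pulse from C into B — then
runs the full discordance pipeline (triplet extraction, topology tallies,
exponential-mixture fits, delta-BIC classification) on the Newick trees.
"""

from discordia import synthetic_data as sd
from discordia import triplet_mixture as tm


def run(label: str, gamma: float) -> None:
    cfg = sd.MscConfig(
        t2=1.0, gamma=gamma,
        donor="C" if gamma else None, recipient="B" if gamma else None,
        n_loci=1500, seed=42,
    )
    trees, _ = sd.simulate_triplet_loci(cfg)
    summary = tm.analyze_triplet(trees, cfg.taxa, cfg.outgroup, seed=0)

    print(f"\n=== {label} (gamma={gamma}) ===")
    print(f"species topology: {'-'.join(summary.species_topology)}")
    for pair, count in sorted(summary.counts.items()):
        fit = summary.fits.get(pair)
        cls = fit.classification if fit else "not fitted"
        print(f"  topology {'-'.join(pair)}: {count:5d} loci  -> {cls}")
    print(f"discordant loci: {summary.n_discordant}")
    print(f"ILS share of discordant loci: {summary.ils_percent:.2f}%")
    print(f"introgression flagged: {summary.introgression_flag}")


if __name__ == "__main__":
    print("Under pure ILS both discordant topologies are ~equally frequent and")
    print("their internal branches fit a single exponential (ils_only).")
    print("With gene flow C->B, the B-C topology is inflated and its branch")
    print("lengths need the shifted mixture component (mixture => flagged).")
    run("pure ILS", gamma=0.0)
    run("ILS + introgression", gamma=0.3)
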