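"""Date LTR retrotransposon insertions from paired-LTR divergence.

Simulates two element cohorts (a recent Copia burst at 0.25 Myr and an older
Gypsy burst at 0.5 Myr) under a two-rate substitution process, estimates K2P
distances between each element's 5' and 3' LTRs, converts them to insertion
ages via T = K/(2 mu), and reports the per-superfamily age density modes.
"""

from discordia import ltr_timing as lt
from discordia import synthetic_data as sd

MU = 1e-8  # substitutions per site per year


def cohort(time_years, n, superfamily, seed0):
    return [
        sd.mutate_ltr_pair(3000, time_years, MU, seed=seed0 + i,
                           element_id=f"{superfamily}_{i}", superfamily=superfamily)
        for i in range(n)
    ]


def main() -> None:
    elements = cohort(0.25e6, 40, "Copia", 0) + cohort(0.5e6, 40, "Gypsy", 1000)

    table = lt.elements_table(elements, mu=MU)
    print(table.groupby("superfamily")[["K", "T"]].mean().round(5))
    print("\nmean K is the pairwise LTR divergence; T = K/(2 mu) in years\n")

    profiles = lt.timing_profile(elements, mu=MU)
    for family, profile in sorted(profiles.items()):
        mode = profile.modes[0]
        print(f"{family}: dominant insertion-age mode at {mode/1e6:.2f} Myr "
              f"({profile.times.size} elements, {profile.n_saturated} saturated)")
    print("\nThe Copia mode near 0.25 Myr and Gypsy mode near 0.5 Myr recover")
    print("the planted burst ages from sequence divergence alone.")


if __name__ == "__main__":
    main()
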