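"""Score the value survey: ipsatized type means and internal consistency.

Reads the cohort written by 01_simulate_cohort.py, centres each
participant's ratings on their own mean, averages the centred ratings
within each of the 10 value types, and tabulates Cronbach's alpha per
type.  Writes results/value_scores.tsv and results/value_alphas.tsv.
"""

from pathlib import Path

from valuewave import value_processing as vp

COHORT = Path("results/cohort")
OUT = Path("results")


def main():
    responses = vp.read_responses(COHORT / "responses.csv")
    item_map = vp.read_item_map(COHORT / "item_map.tsv")
    value_items = [c for c in responses.columns if c in item_map.assignments]

    centered = vp.ipsatize(responses[value_items])
    scores = vp.aggregate_value_types(centered, item_map)
    vp.write_value_scores(scores, OUT / "value_scores.tsv")

    alphas = vp.alpha_by_type(responses[value_items], item_map)
    alphas.to_frame().rename_axis("value_type").to_csv(
        OUT / "value_alphas.tsv", sep="\t"
    )

    print(f"scored {len(scores)} participants on {scores.shape[1]} value types")
    print("\nCronbach's alpha by type:")
    for vt, a in alphas.items():
        print(f"  {vt:<15} {a:.2f}")
    print(f"\nwrote {OUT/'value_scores.tsv'} and {OUT/'value_alphas.tsv'}")


if __name__ == "__main__":
    main()
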