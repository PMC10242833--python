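"""Simulate the reference cohort and check item-level discriminability.

Generates the 500-subject, 60-item synthetic cohort (10 informative items at
ordered-logit shift 1.5), writes it as TSV fixtures under results/cohort/,
and compares each informative item's empirical single-item AUC against the
closed-form value implied by the generative model (0.697 at shift 1.5).
"""

from pathlib import Path

from itemforest import (
    closed_form_item_auc,
    default_cohort_spec,
    generate_cohort,
    single_item_discriminability,
    write_labels,
    write_matrix,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 0


def main() -> None:
    spec = default_cohort_spec(seed=SEED)
    matrix, labels = generate_cohort(spec)
    OUT.mkdir(parents=True, exist_ok=True)
    write_matrix(matrix, OUT / "matrix.tsv", OUT / "items.json")
    write_labels(labels, OUT / "labels.tsv")
    print(f"cohort: {matrix.n_subjects} subjects x {matrix.n_items} items -> {OUT}")
    print(f"{'item':<10}{'shift':>6}{'AUC closed-form':>17}{'AUC empirical':>15}")
    for item in spec.items:
        if item.shift == 0:
            continue
        emp = single_item_discriminability(matrix, labels, item.item_id)
        print(
            f"{item.item_id:<10}{item.shift:>6.1f}"
            f"{closed_form_item_auc(item):>17.3f}{emp:>15.3f}"
        )
    print(
        "\nInformative items sit near the closed-form AUC of 0.697; "
        "null items (not shown) hover at 0.5."
    )


if __name__ == "__main__":
    main()
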