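"""Generate a small synthetic two-group cohort and write it to disk.

Each session bundle is plain text (traces CSV + YAML sidecar) plus
cohort-level ground-truth and cross-day match tables. The "aged" condition
has 1.5x transient amplitudes and initially broader place fields that
sharpen to match the young condition by day 4.
"""

from dgspace import aged_defaults, generate_cohort, write_cohort, young_defaults

young = young_defaults(n_mice=2, cells_per_mouse=10, session_length=120.0)
aged = aged_defaults(n_mice=2, cells_per_mouse=8, session_length=120.0)

cohort = generate_cohort(young, aged, n_days=4, seed=42)
written = write_cohort(cohort, "scratch/example_cohort")

print(f"wrote {len(written)} session bundles to scratch/example_cohort/")
print(f"ground truth: {len(cohort.ground_truth)} cells "
      f"({cohort.ground_truth.is_place_cell.mean():.0%} place cells, "
      f"{cohort.ground_truth.persists_across_days.mean():.0%} persist across days)")
print(cohort.match_table.head(4).to_string(index=False))
print("...")
print("Each match-table row links a day-1 cell to its identity on a later "
      "day; an empty cell_id means the cell was not found again.")
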