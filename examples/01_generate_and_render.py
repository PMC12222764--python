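"""Generate a small synthetic ED cohort and render clinical pseudo-notes.

Writes the six concept CSVs to ./scratch_cohort, reads them back through
the schema layer, and prints the six pseudo-notes of the first encounter.
Each note serializes one EHR concept; missing streams fall back to a fixed
sentence so every encounter always yields six paragraphs.
"""

from meme_ed import make_fixture, read_cohort, render_encounter, cohort_summary
from meme_ed.schema_io import labels_for_cohort

path = make_fixture("scratch_cohort", size="tiny", seed=42)
bundles = read_cohort(path, "mimic_ed")
labels = labels_for_cohort(bundles)

print(f"cohort of {len(bundles)} encounters")
summary = cohort_summary(bundles, labels)
n_admit, pct = summary["outcomes"]["admitted"]
print(f"median age {summary['age_median']:.0f}, "
      f"admitted {n_admit} ({pct}%)\n")

for note in render_encounter(bundles[0]):
    tag = " [fallback]" if note.is_fallback else ""
    print(f"--- {note.concept}{tag}")
    print(note.text[:300])
    print()
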