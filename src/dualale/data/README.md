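# Packaged study metadata

`table2_studies.csv` holds the study-level metadata of the 20 VBM studies of
gray-matter differences in type 1 / type 2 diabetes that the dual-disorder
ALE analysis pools: condition label, group sizes, mean age (patients and
controls), diabetes duration, HbA1c, and the 12-item quality checklist.

Two caveats:

- **Metadata only.** The per-study peak coordinates (foci) were never
  published, so this fixture carries no foci and the coordinate-level
  analysis cannot be reproduced from it; recovery of the spatial pipeline is
  demonstrated on synthetic corpora instead (see `dualale.synthetic`).
- **Item-level quality scores are synthetic.** Only checklist *totals* were
  published. Each total is decomposed deterministically into 12 item scores
  (floor(total) ones, one 0.5 when the total is fractional, zeros elsewhere)
  so the file validates against the checklist schema. Only the totals are
  meaningful.

Missing cells (empty) are genuinely unreported values. `duration_is_median=1`
flags a study that reported a median duration rather than a mean; it is
pooled as-is.
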