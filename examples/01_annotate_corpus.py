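"""Annotate a synthetic element corpus end to end.

Builds a small ground-truth corpus (reference domain database, tRNA library
and elements with known structure), runs the full annotation chain, and
prints the per-element classification next to the generated truth.
"""

from ltrkit import annotate
from ltrkit.lineage_classify import format_report
from ltrkit.synth_fixtures import make_corpus

elements, manifests, refdb, trnas = make_corpus(6, seed=4)
records = annotate(elements, refdb, trnas)

df, summary = format_report(records)
print(df[["element", "superfamily", "lineage", "pbs_mode", "pbs_trna", "tsd_len"]].to_string(index=False))
print()
for rec, m in zip(records, manifests):
    mark = "ok" if rec.lineage.lineage_path == m.lineage_path else "MISMATCH"
    print(f"{rec.seq.id}: generated {m.lineage_path} -> called {rec.lineage.lineage_path} [{mark}]")
print()
print("lineage counts:", summary["lineage_counts"])
# Each row shows what the pipeline recovered for one element; the ok marks
# confirm the classification equals the lineage each element was built from.
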