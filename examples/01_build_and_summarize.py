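"""Build an incidence matrix from a long nominal table and summarize it.

A drug-response style table (drug, patient, response) is aggregated into a
bipartite incidence matrix whose missing cells are *unknown* interactions,
then summarized and degree-filtered.
"""

import tempfile
from pathlib import Path

from gapmine import build_incidence, filter_by_degree, read_nominal_table, summarize_incidence

csv = """\
dasatinib,p01,0.82
dasatinib,p02,0.40
dasatinib,p03,0.71
sorafenib,p01,0.15
sorafenib,p02,0.33
venetoclax,p02,0.91
venetoclax,p03,0.27
venetoclax,p03,0.31
quizartinib,p04,0.55
"""

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "responses.csv"
    path.write_text(csv)
    table = read_nominal_table(path)

M = build_incidence(table, agg="mean")  # duplicate (venetoclax, p03) averaged
s = summarize_incidence(M)
print(f"incidence matrix: {s.n_rows} drugs x {s.n_cols} patients")
print(f"observed cells: {s.n_observed} ({s.prop_nonmissing:.0%} non-missing)")
print(f"weight range: {s.weight_range}")
# the complement (here 50%) is the missingness whose *shape* the rest of the
# package analyses

core = filter_by_degree(M, min_row_deg=2, min_col_deg=2, iterative=True)
print(f"stable core after degree filtering: {core.shape[0]} x {core.shape[1]}")
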