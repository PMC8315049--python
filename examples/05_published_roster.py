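"""Summarize the packaged published response-profile roster.

The fixture carries the 188 grouped proteins (32 Group I, 64 Group II,
92 Group III), each with its dexamethasone direction, plus the three
proteins listed only for their consistent Dex effect.
"""

import cartisec as cs
from cartisec.grouping import roster_to_assignments, summarize

roster = cs.load_table1_roster()
grouped = [e for e in roster if e.group is not None]
print(f"roster entries: {len(roster)} ({len(grouped)} grouped)")

summary = summarize(roster_to_assignments(roster))
print(f"groups: I={summary.n_I} II={summary.n_II} III={summary.n_III}")
print(f"increased release: {summary.pct_increased}%  "
      f"decreased: {summary.pct_decreased}%")
print(f"Dex-decreased: {summary.n_dex_decreased} ({summary.pct_dex_decreased}%), "
      f"Dex-increased: {summary.n_dex_increased} ({summary.pct_dex_increased}%)")
print(f"Group III reduced by Dex: {summary.pct_III_dex_reduced}%")

consistent = [e for e in roster if e.dex_consistent]
print("consistent Dex effects:",
      ", ".join(f"{e.gene_symbol} ({e.dex_consistent})" for e in consistent))
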