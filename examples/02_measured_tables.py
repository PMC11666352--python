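"""Explore the packaged multiparametric measurements of 46 Taq mutants + WT.

Run:  python examples/02_measured_tables.py
"""

from taqdesign import (correlation_matrix, count_detectable,
                       count_exceeding_reference, load_study_tables,
                       squared_pearson)

table = load_study_tables()
print(f"{len(table)} enzymes x {len(table.properties)} properties "
      f"(rounds: {sorted(table.rounds.unique())})")
print(f"WT fidelity: {table.values.at['WT', 'fidelity']:,.2f} nt/error")

# short-template reverse-transcription activities track each other closely
r2 = squared_pearson(table, "rt90", "rt116")
print(f"r^2(dCq 90 nt, dCq 116 nt) over all exactly measured rows: {r2:.3f}")

# counts behind the campaign's headline observations (round I table alone)
from pathlib import Path
import taqdesign.dataset
from taqdesign.dataset import load_property_table
t1 = load_property_table(Path(taqdesign.dataset.__file__).parent / "data" / "table1.tsv")
print(f"Mutants beating WT on both short templates: "
      f"{count_exceeding_reference(t1, ['rt90', 'rt116'], 'WT', 'lower')}")
print(f"Detectable 526-nt cDNA: {count_detectable(t1, 'rt526')} of {len(t1)}")

# the trade-off structure: stronger RTase activity (lower dCq) comes with
# lower K_d, lower fidelity, better dU incorporation
rho = correlation_matrix(table, "spearman")
for prop in ("kd", "fidelity", "dTdU_rate", "kcat_dT"):
    print(f"  spearman(dCq 90 nt, {prop}) = {rho.at['rt90', prop]:+.2f}")
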