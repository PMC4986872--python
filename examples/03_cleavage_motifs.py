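"""Differential cleavage-site logos and consensus strings.

Extracts -20..+10 windows around the mature N-termini of the ICP55
substrates from the published tables, contrasts the per-position residue
frequencies against the proteome background (percentage-point differences
with a proportion z-test per cell) and prints the consensus motif.
"""

from mitonterm.calling import StabilityTable, call_icp55_all
from mitonterm.filtering import run_filters
from mitonterm.fixtures import load_fixtures
from mitonterm.io import map_peptides
from mitonterm.motifs import (
    build_pfm,
    consensus_string,
    extract_window,
    icelogo_diff,
    reference_frequencies,
)

bundle = load_fixtures()
mapped, _ = map_peptides(bundle.peptides["icp55"], bundle.proteins)
_, retained, _ = run_filters(mapped, bundle.localization, bundle.proteins)
calls = call_icp55_all(retained, bundle.proteins,
                       stability=StabilityTable().with_unstable("MC"))

windows = [extract_window(bundle.proteins[c.accession].sequence,
                          c.mature_start) for c in calls]
reference = reference_frequencies(bundle.proteins.values())
profile = icelogo_diff(build_pfm(windows), reference)

print(f"windows: {len(windows)} (one per substrate protein)")
print(f"consensus: {consensus_string(profile)}")
print()
print("strongest enrichments near the cleavage site "
      "(position, residue, +percentage points, p):")
for pos in (-3, -2, -1, 1, 2):
    diff = profile.difference[pos]
    aa = diff.idxmax()
    print(f"  {pos:+d}\t{aa}\t{diff[aa]:+.1f}\t{profile.p_values[pos][aa]:.2e}")
# The arrow in the consensus marks the cleavage point: residues left of it
# are the end of the presequence (the last one is what ICP55 removed),
# residues right of it start the mature protein.
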