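"""Deduplicate merged ancient-style reads, then derive depth thresholds.

Builds a small synthetic reference and read set with 30% planted PCR
duplicates, removes them by the start+end coordinate rule, and derives
the per-sample depth window (1/3x .. 10x of the average, absolute
minimum 3) used by the downstream variant filters.
"""

from erodekit.dedup import remove_duplicates
from erodekit.depthqc import average_depth, depth_profile, depth_thresholds
from erodekit.simulate import simulate_alignments, simulate_reference

ref = simulate_reference(50_000, seed=1).objects["reference"]
bundle = simulate_alignments(ref, mean_depth=12, dup_rate=0.3, seed=1)
reads = bundle.objects["alignments"]

kept, n_removed, hist = remove_duplicates(reads)
print(f"reads in: {len(reads)}, kept: {len(kept)}, duplicates removed: {n_removed}")
print(f"planted duplicates: {bundle.truth['n_duplicates']} (must match exactly)")
print(f"cluster sizes: { {k: hist[k] for k in sorted(hist)} }")

profile = depth_profile(kept, {ref.name: ref.length})
avg = average_depth(profile, include_zero=True)
thr = depth_thresholds(avg)
print(f"post-dedup average depth: {avg:.2f}")
print(f"depth window for filtering: [{thr.min_depth:.2f}, {thr.max_depth:.2f}]")
# The window means: genotypes at sites with DP outside it are discarded —
# low depth gives unreliable calls, very high depth flags collapsed repeats.
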