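"""End-to-end workflow: mine -> GWAS -> linkage groups -> marker validation.

Runs the whole chain on a synthetic population with a duplex causal locus
(the two copies on different homologs of chromosome 1, each tagged by
coupling-phase simplex SNPs), then checks that the significant markers
fall into two homolog linkage groups and cosegregate with the bimodal
trait classes.
"""

from hexadose.association import bonferroni_threshold, glm_scan, significant_markers
from hexadose.linkage import all_pairs, group_markers, order_markers
from hexadose.mining import mine_single_dose
from hexadose.pipeline import assign_parent_of_origin
from hexadose.segtest import classify_phenotype_bimodal, cosegregation_check, gof_chi2
from hexadose.simulate import simulate_dataset

PARENTS = ("P1", "P2")
counts, phenotype, scenario, f1 = simulate_dataset(seed=1)
progeny = [s for s in counts.samples if s not in PARENTS]

# 1. single-dose marker mining
markers, _ = mine_single_dose(counts, parent_samples=PARENTS)
print(f"{len(markers)} single-dose markers retained")

# 2. trait segregation: dominant duplex locus -> 4:1 low:high classes
classes = classify_phenotype_bimodal(phenotype, low_cut=2.2, high_cut=29.6)
n_low = int((classes["klass"] == "low").sum())
n_high = int((classes["klass"] == "high").sum())
seg = gof_chi2([n_low, n_high], [4, 1])
print(f"trait classes {n_low} low : {n_high} high vs 4:1 -> "
      f"chi2 = {seg.chi2:.2f}, P = {seg.p_value:.2f}")

# 3. single-marker GLM scan with Bonferroni control
results = glm_scan(markers, phenotype, progeny)
threshold = bonferroni_threshold(0.05, len(results))
hits, by_type = significant_markers(results, threshold)
print(f"{len(hits)} significant markers at P < {threshold:.2e} "
      f"(by cross type: {dict(by_type)})")
top = hits[0]
print(f"top hit {top.marker}: F = {top.f_stat:.1f}, P = {top.p_value:.2e}")

# 4. linkage groups among same-parent simplex significant markers
by_id = {m.marker_id: m for m in markers}
p1_hits = [by_id[h.marker] for h in hits
           if by_id[h.marker].is_simplex
           and assign_parent_of_origin(counts, by_id[h.marker], PARENTS) == "P1"]
pairs = all_pairs(p1_hits)
groups = group_markers([m.marker_id for m in p1_hits], pairs)
print(f"{len(p1_hits)} significant simplex markers from P1 -> {len(groups)} linkage groups")
for gi, g in enumerate(groups, 1):
    ordered = order_markers(g, pairs)
    span = ordered.positions_cm[-1]
    print(f"  group {gi}: {len(g)} markers spanning {span:.1f} cM")

# 5. validate the top marker: cosegregation with the low-trait class
marker_presence = (by_id[top.marker].codes == 1).astype(int)
marker_presence[by_id[top.marker].codes == -1] = -1
status = (classes["klass"].reindex(progeny) == "low").astype(int).to_numpy()
co = cosegregation_check(marker_presence, status)
print(f"top marker vs low-trait class: {co.recombinants}/{co.n} recombinants "
      f"({co.orientation} phase)")
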