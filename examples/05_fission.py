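"""Tubulation and fission detection on a scripted pulling movie.

Generates a kinematic movie of a membrane patch pulled into a ~700 Å tube
whose neck severs at 80 ns, then detects the fission two independent ways:
a changepoint (inflection) in the elongation trace, and the topological
split of the lipid cloud into two clusters. Both should agree with the
scripted time.
"""

import memfission as mf
from memfission.fission import PatchSelection

series = mf.gen_tubulation_movie(seed=21)   # fission scripted at 80 ns
prov = series.provenance

patch = PatchSelection(lipid_ids=prov["patch_lipid_ids"],
                       center=(0.0, 0.0), radius=30.0)
trace = mf.elongation_trace(series, patch, prov["base_lipid_ids"])
inflection = mf.detect_inflection(trace)
event = mf.detect_fission_topology(series)

print(f"scripted fission time   : 80.0 ns")
print(f"inflection detected at  : {inflection.time:.1f} ns, "
      f"elongation {inflection.elongation_at_inflection:.0f} Å")
print(f"slopes pre/post         : {inflection.slope_pre:.2f} → "
      f"{inflection.slope_post:.2f} Å/ns")
print(f"topological split frame : {event.frame} "
      f"(scripted {prov['fission_frame']})")
print("The released tube travels faster than it grew — that slope jump at "
      "~700 Å elongation is the fission signature in the trace.")
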