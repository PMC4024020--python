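"""Run the complete analysis pipeline on a generated model.

Writes every stage's table (drivers, link classes, modules, roles,
centralities, profiles) plus a JSON summary into an output directory and
prints the headline numbers.  Rerunning with the same seed reproduces
the summary exactly.
"""

import json
import tempfile
from pathlib import Path

from netctrl import (
    RunConfig,
    SyntheticModelSpec,
    generate_reactions,
    run_full_analysis,
    serialize_reactions,
)

workdir = Path(tempfile.mkdtemp(prefix="netctrl_demo_"))
model = workdir / "model.txt"
model.write_text(serialize_reactions(generate_reactions(SyntheticModelSpec(
    n_metabolites=60, n_reactions=85, fraction_boundary=0.06,
    fraction_transport=0.25, seed=5,
))))

summary = run_full_analysis(RunConfig(
    reactions_path=str(model), out_dir=str(workdir / "out"),
    n_samples=300, seed=7,
))
print(f"outputs in {workdir / 'out'}:")
for p in sorted((workdir / "out").iterdir()):
    print(f"  {p.name}")
keep = {k: summary[k] for k in ("network", "drivers", "link_classes", "control_mode", "modules")}
print(json.dumps(keep, indent=2, default=float))
print("drivers/class_counts gives the critical / high- / low-frequency "
      "driver metabolite split; modules/modularity is the annealed M")
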