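"""Run the whole pipeline from files on disk.

Writes a simulated dataset as the five TSV inputs (PPI edges, domain
annotation, DDI catalog, mutation counts, expression matrix + labels),
then runs score -> signatures -> features -> nested CV through
run_pipeline and lists the artifacts it produced.
"""

import json
import tempfile
from pathlib import Path

from domainsig import (
    RunConfig,
    SimConfig,
    run_pipeline,
    simulate_bundle,
    simulate_cohort,
    write_simulation,
)

workdir = Path(tempfile.mkdtemp(prefix="domainsig_"))
cfg = SimConfig(seed=42, n_patients_good=30, n_patients_poor=20)
bundle, truth = simulate_bundle(cfg)
cohort = simulate_cohort(bundle, truth, cfg)
inputs = write_simulation(bundle, truth, cohort, workdir / "inputs")
print("inputs written:")
for name, path in inputs.items():
    print(f"  {name:<13} {path}")

run_cfg = RunConfig(
    ppi=str(inputs["ppi"]),
    annotation=str(inputs["annotation"]),
    ddi=str(inputs["ddi"]),
    mutations=str(inputs["mutations"]),
    expression=str(inputs["expression"]),
    labels=str(inputs["labels"]),
    outdir=str(workdir / "out"),
    seed=42,
    c_grid=(30, 50, 80),
)
artifacts = run_pipeline(run_cfg)
print("\nartifacts:")
for name, path in artifacts.items():
    print(f"  {name:<13} {path}")

report = json.loads(artifacts["cv_report"].read_text())
print(f"\npooled accuracy {report['pooled']['accuracy']:.3f}, "
      f"AUC {report['auc']:.3f} "
      f"(chosen c per fold: {[f['chosen_c'] for f in report['folds']]})")
print("Re-running with the same seed reproduces every file byte for byte.")
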