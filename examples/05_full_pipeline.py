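"""Run the whole pipeline from one configuration and verify determinism.

Equivalent to `proteoruler run --config cfg.yaml`.  All stage outputs are
written as TSV under the output directory together with a JSON manifest of
SHA-256 hashes; the same config and seed always reproduce the same bytes.
"""

import tempfile
from pathlib import Path

import proteoruler as pr

with tempfile.TemporaryDirectory() as tmp:
    cfg = pr.RunConfig(out_dir=str(Path(tmp) / "run"), seed=7, n_proteins=500)
    manifest = pr.run_pipeline(cfg)
    print(f"wrote {len(manifest['artifacts'])} artifacts:")
    for name in manifest["artifacts"]:
        print(f"  {name}")

    again = pr.run_pipeline(
        pr.RunConfig(out_dir=str(Path(tmp) / "run2"), seed=7, n_proteins=500)
    )
    print("\nidentical manifests on re-run:",
          manifest["artifacts"] == again["artifacts"])
    print("-> byte-identical outputs under a fixed seed; change the seed "
          "and only the noise realisation changes, not the planted truth "
          "structure.")
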