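#!/usr/bin/env python
"""Generate the synthetic dyad datasets the downstream analyses consume.

Writes one small HDF5 dataset per simulation profile to scratch/fixtures
(binary data stays out of the deliverable tree) and a manifest of the
ground-truth settings to results/.

Profiles: `intra_effect` (default generator: 20% infant JA amplitude
boost over the central-occipital-parietal scalp), `null` (no condition
differences anywhere), `coupling` (strong JA-only envelope coupling),
and `tiny` (a 12-image session for quick inspection).
"""

import json
from pathlib import Path

from dyadssvep.pipeline import FIXTURE_PROFILES, make_fixtures

SEED = 7
OUT = Path("scratch/fixtures")
RESULTS = Path("results")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    summary = {}
    for profile in FIXTURE_PROFILES:
        manifest = make_fixtures(profile, seed=SEED, out_dir=OUT / profile)
        summary[profile] = {
            "n_dyads": len(manifest["paths"]),
            "rho": manifest["config"]["envelope_coupling"],
            "amplitude": manifest["config"]["amplitude"],
        }
        print(f"{profile}: {len(manifest['paths'])} dyads -> {OUT / profile}")
    (RESULTS / "fixture_manifest.json").write_text(json.dumps(summary, indent=2))
    print(f"ground-truth summary -> {RESULTS / 'fixture_manifest.json'}")


if __name__ == "__main__":
    main()
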