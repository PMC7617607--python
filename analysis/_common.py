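"""Shared study definition and paths for the numbered analysis drivers.

The study emulates a cis-pQTL screen of coagulation-cascade proteins against
venous thromboembolism (VTE, the liability trait) and ischemic stroke (the
primary outcome): eight proteins with one strong cis signal each, of which
three causally raise stroke risk and five act on VTE only.
"""

from pathlib import Path

from coagmr.calibration import make_benchmark_config
from coagmr.report import DataBundle

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
FIXTURE = SCRATCH / "fixture"

STUDY_SEED = 7


def study_config():
    return make_benchmark_config(STUDY_SEED, n_causal=3, n_vte_only=5)


def get_bundle() -> DataBundle:
    """Prefer the on-disk fixture written by 01_simulate.py; otherwise
    regenerate the identical data in memory."""
    if (FIXTURE / "config.yaml").exists():
        return DataBundle.from_fixture(FIXTURE)
    bundle, _ = DataBundle.from_simulation(study_config())
    return bundle
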