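"""Write the synthetic GWAS fixture for the study (sumstats, LD, gene BED).

Large generated files live under scratch/ (regenerable at any time); the
ground truth used for later scoring is part of the fixture (truth.json).
"""

from _common import FIXTURE, study_config

from coagmr.simulate import write_fixture


def main() -> None:
    config = study_config()
    out = write_fixture(config, FIXTURE, force=True)
    n_files = sum(1 for p in out.rglob("*") if p.is_file())
    print(f"fixture written to {out} ({n_files} files, seed {config.seed})")


if __name__ == "__main__":
    main()
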