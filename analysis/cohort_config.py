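"""Shared study configuration for the numbered analysis scripts.

One seed, 3 control + 3 treated synthetic animals, default geometry and
acquisition (20 TIs on a 100 ms R-R grid, the five SE and four UTE echo
times, SNR 30). Every script derives its inputs deterministically from this
configuration, so the scripts can be run independently in order.
"""

from cardiomap.pipeline import RunConfig

OUTPUT_DIR = "results/cohort"


def study_config() -> RunConfig:
    return RunConfig(seed=2026, n_control=3, n_treated=3, output_dir=OUTPUT_DIR)


def animal_list(config: RunConfig):
    return ([(f"control_{i}", i, False) for i in range(config.n_control)]
            + [(f"treated_{i}", config.n_control + i, True)
               for i in range(config.n_treated)])
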