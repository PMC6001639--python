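"""Bundled benchmark dataset."""

from __future__ import annotations

from importlib import resources

from .data import NetworkTable, read_arm_table

__all__ = ["load_smoking"]


def load_smoking() -> NetworkTable:
    """The classic smoking-cessation network (Hasselblad 1998).

    24 randomized trials comparing 4 interventions to aid smoking cessation
    (1 = no contact, 2 = self-help, 3 = individual counselling, 4 = group
    counselling), with the number of successful quitters out of the patients
    per arm.  Two trials have three arms; the network has 8 designs.  A
    standard benchmark for network meta-analysis inconsistency models.
    """
    ref = resources.files("nmala").joinpath("data/smoking.csv")
    with resources.as_file(ref) as path:
        return read_arm_table(path, family="binomial", sep=",")
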