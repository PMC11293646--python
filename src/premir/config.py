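"""Tunable thresholds of the qualification and rule stages.

Every threshold has the field-standard default: the final rule engine
defaults encode the generally accepted plant miRNA criteria (2-nt 3'
overhangs, no secondary stems, at most 6 mismatched duplex positions with
at most 3 of them in asymmetric bulges, precursor <= 300 nt, mature
20-24 nt, optional banned mismatch positions such as 9-11); the primary
qualification filter demands an uninterrupted near-perfect stem and a
simple terminal loop with at most 3 terminal structures.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

__all__ = ["RuleConfig", "QualConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class RuleConfig:
    overhang_nt: int = 2
    max_mismatch: int = 6
    max_asym: int = 3
    max_precursor_len: int = 300
    min_mature_len: int = 20
    max_mature_len: int = 24
    banned_mismatch_positions: tuple[int, ...] = ()
    allow_secondary_stems: bool = False
    wobble_is_pair: bool = True

    def __post_init__(self):
        if self.min_mature_len > self.max_mature_len:
            raise ValueError("min_mature_len exceeds max_mature_len")
        if self.max_asym > self.max_mismatch:
            raise ValueError("max_asym cannot exceed max_mismatch")


@dataclass(frozen=True)
class QualConfig:
    """Primary qualification filter thresholds."""

    min_stem_frac: float = 0.2        # below this the hit is "not in a stem"
    min_paired_frac: float = 0.6      # near-perfect complementarity
    max_unpaired_run: int = 5         # continuous complementary region
    max_terminal_structures: int = 3  # simple terminal loop
    max_internal_loop_side: int = 5   # large internal loops in the duplex

    def __post_init__(self):
        if not 0 <= self.min_stem_frac <= self.min_paired_frac <= 1:
            raise ValueError("need 0 <= min_stem_frac <= min_paired_frac <= 1")


def load_config(text: str) -> dict:
    """Flat key/value YAML into a dict of config sections."""
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    return data


def dump_config(rule: RuleConfig, qual: QualConfig, extra: dict | None = None) -> str:
    payload = {"rules": asdict(rule), "qualification": asdict(qual)}
    if extra:
        payload.update(extra)
    payload["rules"]["banned_mismatch_positions"] = list(
        rule.banned_mismatch_positions
    )
    return yaml.safe_dump(payload, sort_keys=True)
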