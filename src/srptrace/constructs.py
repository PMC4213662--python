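"""Parametric models of mRNA constructs and kinetic/optical configurations.

The experiment these configurations describe: pre-initiation complexes are
immobilized on a 3'-truncated ``lepB`` mRNA inside zero-mode waveguides; dye
labeled 50S subunits, SRP and (optionally) labeled Phe-tRNA ternary complexes
are delivered at t = 0.  The ribosome elongates codon by codon; once the
nascent chain grows long enough for the signal sequence to emerge from the
exit tunnel, SRP association accelerates sharply.  Everything the simulator
and the analysis need to know about a construct and a reaction condition
lives in the three dataclasses below.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import yaml

CONFIG_SCHEMA = "srptrace-config/1"

#: Chain length (aa) at which a functional signal sequence starts promoting
#: fast SRP association, and the length at which the ramp tops out.
DEFAULT_EXPOSURE_AA = 40
DEFAULT_RAMP_END_AA = 55


@dataclass(frozen=True)
class MRNAConstruct:
    """A 3'-truncated mRNA construct with optional labeled-Phe landmarks.

    Parameters
    ----------
    name:
        Construct label.
    length_aa:
        Number of encoded amino acids (the ribosome run-off stalls here).
    phe_positions:
        Ordered 1-based codon indices decoded by the labeled Phe-tRNA.
    signal_functional:
        Whether the encoded signal sequence is functional (mutant constructs
        never trigger the fast-association ramp).
    exposure_aa, ramp_end_aa:
        Chain lengths bracketing the association-rate ramp.
    """

    name: str
    length_aa: int
    phe_positions: tuple[int, ...] = ()
    signal_functional: bool = True
    exposure_aa: int = DEFAULT_EXPOSURE_AA
    ramp_end_aa: int = DEFAULT_RAMP_END_AA

    def __post_init__(self) -> None:
        if self.length_aa <= 0:
            raise ValueError("length_aa must be positive")
        pp = tuple(int(p) for p in self.phe_positions)
        if any(b <= a for a, b in zip(pp, pp[1:])):
            raise ValueError("phe_positions must be strictly increasing")
        if pp and (pp[0] < 1 or pp[-1] > self.length_aa):
            raise ValueError("phe_positions must lie in [1, length_aa]")
        if not (self.exposure_aa < self.ramp_end_aa <= self.length_aa):
            raise ValueError("require exposure_aa < ramp_end_aa <= length_aa")
        object.__setattr__(self, "phe_positions", pp)

    @property
    def landmark_runs(self) -> tuple[tuple[int, int], ...]:
        """Maximal runs of consecutive landmark codons as (first, last)."""
        runs: list[tuple[int, int]] = []
        for p in self.phe_positions:
            if runs and p == runs[-1][1] + 1:
                runs[-1] = (runs[-1][0], p)
            else:
                runs.append((p, p))
        return tuple(runs)


_CWT_LANDMARKS = (5, 25, 26, 27, 55, 56, 57, 85, 86, 87)

_NAMED_CONSTRUCTS = {
    # full-length truncation used for the uncalibrated arrival experiments
    "lepB155": dict(length_aa=155, phe_positions=(), signal_functional=True),
    # calibration constructs: 95 aa with Phe landmarks at 5, 25-27, 55-57, 85-87
    "cWT": dict(length_aa=95, phe_positions=_CWT_LANDMARKS, signal_functional=True),
    "cMT": dict(length_aa=95, phe_positions=_CWT_LANDMARKS, signal_functional=False),
}


def default_construct(name: str) -> MRNAConstruct:
    """Return one of the named constructs (``lepB155``, ``cWT``, ``cMT``)."""
    try:
        kw = _NAMED_CONSTRUCTS[name]
    except KeyError:
        raise ValueError(
            f"unknown construct {name!r}; valid names: "
            + ", ".join(sorted(_NAMED_CONSTRUCTS))
        ) from None
    return MRNAConstruct(name=name, **kw)


@dataclass(frozen=True)
class KineticConfig:
    """Rates and times governing one reaction condition.

    ``koff_bins`` maps chain-length intervals to dissociation rates: a list of
    ``(lo, hi, rate)`` triples, left-closed, covering [0, inf).  The default
    rates are the reciprocals of the measured per-bin residence lifetimes,
    longest (most stable binding) in the 50-60 aa window where the signal
    sequence is optimally presented.

    Default elongation speeds (6.3 s/aa at 750 nM EF-G, 7.9 s/aa at
    250 nM) sit inside the 5-10 s/aa range expected for these factor
    concentrations; Phe landmark codons are slower (10 s) because the
    labeled ternary complex is supplied at only 200 nM.
    """

    srp_conc: float = 100e-9          # M, labeled SRP
    dwell_mean_nonphe: float = 6.3    # s per ordinary codon
    dwell_mean_phe: float = 10.0      # s per labeled-Phe codon
    kon_pre: float = 3.4e3            # M-1 s-1 before signal-sequence exposure
    kon_post: float = 1.8e6           # M-1 s-1 once fully exposed
    koff_bins: tuple[tuple[float, float, float], ...] = (
        (0.0, 40.0, 0.067),
        (40.0, 50.0, 0.0288),
        (50.0, 60.0, 0.0134),
        (60.0, 70.0, 0.0265),
        (70.0, math.inf, 0.03),
    )
    bleach_mean_donor: float = 5000.0  # s, donor photobleach
    join_mean: float = 5.0             # s, 50S joining after delivery
    duration: float = 1200.0           # s, recorded trace length
    frame_interval: float = 0.1        # s (100 ms camera resolution)
    stalled_mode: bool = False
    rnc_heterogeneity_sd: float = 0.0  # log-scale per-RNC rate multiplier
    deterministic_dwells: bool = False  # zero dwell variance (test mode)

    def __post_init__(self) -> None:
        for name in (
            "srp_conc", "dwell_mean_nonphe", "dwell_mean_phe", "kon_pre",
            "kon_post", "bleach_mean_donor", "join_mean", "duration",
            "frame_interval",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.kon_pre >= self.kon_post:
            raise ValueError("kon_pre must be < kon_post")
        if self.frame_interval > self.duration:
            raise ValueError("frame_interval must not exceed duration")
        if self.rnc_heterogeneity_sd < 0:
            raise ValueError("rnc_heterogeneity_sd must be >= 0")
        bins = tuple((float(a), float(b), float(r)) for a, b, r in self.koff_bins)
        if not bins or bins[0][0] != 0.0 or not math.isinf(bins[-1][1]):
            raise ValueError("koff_bins must cover [0, inf)")
        for (a, b, r), nxt in zip(bins, bins[1:] + ((None, None, None),)):
            if not b > a:
                raise ValueError("koff_bins intervals must be non-empty")
            if r <= 0:
                raise ValueError("dissociation rates must be strictly positive")
            if nxt[0] is not None and nxt[0] != b:
                raise ValueError("koff_bins must tile without gaps or overlap")
        object.__setattr__(self, "koff_bins", bins)

    def koff_at(self, chain_aa: float) -> float:
        """Dissociation rate (s^-1) for a binding event starting at chain_aa."""
        if chain_aa < 0:
            raise ValueError("chain_aa must be >= 0")
        for lo, hi, rate in self.koff_bins:
            if lo <= chain_aa < hi:
                return rate
        return self.koff_bins[-1][2]


def default_kinetics(ef_g_nm: int = 750, **overrides) -> KineticConfig:
    """Kinetic configuration for one of the two EF-G concentrations used.

    Elongation is slower at 250 nM EF-G; every other rate is shared.
    """
    if ef_g_nm == 750:
        dwell = 6.3
    elif ef_g_nm == 250:
        dwell = 7.9
    else:
        raise ValueError("ef_g_nm must be 750 or 250")
    overrides.setdefault("dwell_mean_nonphe", dwell)
    return KineticConfig(**overrides)


@dataclass(frozen=True)
class OpticsConfig:
    """Rendering model for the three fluorescence channels.

    The bound-state FRET efficiency is a two-component normal mixture (the
    complex adopts at least two conformations on the ribosome); the ZMW
    aluminum walls quench the acceptor by ``zmw_quench``, which maps the
    corrected 0.33-0.5 efficiency range onto the observed 0.2-0.32 range.
    """

    donor_amp: float = 300.0    # AU, donor while the 50S is joined and unbleached
    trna_amp: float = 200.0     # AU, tRNA channel during landmark occupancy
    noise_sd: float = 30.0      # AU additive Gaussian noise per channel/frame
    efret_means: tuple[float, ...] = (0.26, 0.42)
    efret_sds: tuple[float, ...] = (0.05, 0.05)
    efret_weights: tuple[float, ...] = (0.5, 0.5)
    forster_radius: float = 65.0  # Angstrom
    zmw_quench: float = 0.65      # acceptor attenuation in ZMW mode, (0, 1]
    crosstalk: float = 0.0        # donor->acceptor spectral crosstalk hook

    def __post_init__(self) -> None:
        if len(self.efret_means) != len(self.efret_sds) or len(
            self.efret_means
        ) != len(self.efret_weights):
            raise ValueError("efret mixture components must align")
        if any(not 0 < m < 1 for m in self.efret_means):
            raise ValueError("efret component means must lie in (0, 1)")
        if abs(sum(self.efret_weights) - 1.0) > 1e-9:
            raise ValueError("efret weights must sum to 1")
        if not 0 < self.zmw_quench <= 1:
            raise ValueError("zmw_quench must lie in (0, 1]")
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be positive")
        if self.noise_sd < 0 or self.donor_amp <= 0 or self.trna_amp <= 0:
            raise ValueError("amplitudes must be positive, noise_sd >= 0")


def kon_at(construct: MRNAConstruct, config: KineticConfig, chain_aa: float) -> float:
    """SRP association rate (M^-1 s^-1) at a given nascent-chain length.

    Below ``exposure_aa`` the rate is the slow ``kon_pre``; at or beyond
    ``ramp_end_aa`` it is the fast ``kon_post``; in between it rises
    log-linearly (the signal sequence emerges gradually over ~15 codons).
    Constructs without a functional signal sequence stay at ``kon_pre``
    at every chain length.
    """
    if chain_aa < 0:
        raise ValueError("chain_aa must be >= 0")
    if not construct.signal_functional:
        return config.kon_pre
    if chain_aa < construct.exposure_aa:
        return config.kon_pre
    if chain_aa >= construct.ramp_end_aa:
        return config.kon_post
    frac = (chain_aa - construct.exposure_aa) / (
        construct.ramp_end_aa - construct.exposure_aa
    )
    return config.kon_pre * (config.kon_post / config.kon_pre) ** frac


@dataclass(frozen=True)
class FullConfig:
    """Bundle of construct + kinetics + optics + master seed."""

    construct: MRNAConstruct = field(default_factory=lambda: default_construct("cWT"))
    kinetics: KineticConfig = field(default_factory=default_kinetics)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    seed: int = 0

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "schema": CONFIG_SCHEMA,
            "construct": dataclasses.asdict(self.construct),
            "kinetics": dataclasses.asdict(self.kinetics),
            "optics": dataclasses.asdict(self.optics),
            "seed": int(self.seed),
        }
        # JSON/YAML have no inf literal across dialects; encode open end as null
        kb = [
            [lo, None if math.isinf(hi) else hi, r]
            for lo, hi, r in self.kinetics.koff_bins
        ]
        d["kinetics"]["koff_bins"] = kb
        d["construct"]["phe_positions"] = list(self.construct.phe_positions)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FullConfig":
        schema = d.get("schema")
        if schema != CONFIG_SCHEMA:
            raise ValueError(
                f"unrecognized config schema {schema!r} (expected {CONFIG_SCHEMA})"
            )
        c = dict(d.get("construct", {}))
        k = dict(d.get("kinetics", {}))
        o = dict(d.get("optics", {}))
        if "phe_positions" in c:
            c["phe_positions"] = tuple(c["phe_positions"])
        if "koff_bins" in k:
            k["koff_bins"] = tuple(
                (lo, math.inf if hi is None else hi, r) for lo, hi, r in k["koff_bins"]
            )
        for key in ("efret_means", "efret_sds", "efret_weights"):
            if key in o:
                o[key] = tuple(o[key])
        try:
            return cls(
                construct=MRNAConstruct(**c),
                kinetics=KineticConfig(**k),
                optics=OpticsConfig(**o),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as exc:
            raise ValueError(f"invalid config: {exc}") from exc

    def save(self, path) -> None:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)

    @classmethod
    def load(cls, path) -> "FullConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_dict(d)

    def replace(self, **kw) -> "FullConfig":
        return dataclasses.replace(self, **kw)
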