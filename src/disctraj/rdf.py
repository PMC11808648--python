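"""Radial distribution functions and the PMF transform −RT ln g(r).

Two normalizations are offered because a finite nanodisc in water has no
true bulk density: ``box_density`` divides by the ideal-gas expectation at
the box's mean target density (the conventional g(r)); ``tail_unit``
rescales so the mean of g over the last 10% of bins is 1.  The two differ
by a constant factor, so PMF *depths* depend on the mode (effective /
qualitative numbers) while the minimum *location* does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._neighbors import pairs_within
from .contacts import InvalidGroupsError
from .model import ConfigurationError, Trajectory

#: Gas constant, kJ·mol⁻¹·K⁻¹.
GAS_CONSTANT = 8.314462618e-3

NORMALIZATIONS = ("box_density", "tail_unit")


@dataclass
class RDFProfile:
    bin_centers: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    normalization: str
    r_max: float
    bin_width: float
    n_reference: int
    n_target: int
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(r=self.bin_centers, g=self.g,
                                 counts=self.counts))


@dataclass
class PMFProfile:
    """PMF defined only where g > 0 (NaN elsewhere)."""

    bin_centers: np.ndarray
    pmf: np.ndarray
    temperature: float
    minimum: Tuple[float, float]  # (depth kJ/mol, location Å)
    normalization: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(r=self.bin_centers, pmf=self.pmf,
                                 defined=np.isfinite(self.pmf)))


def rdf(
    traj: Trajectory,
    reference,
    target,
    r_max: float = 15.0,
    bin_width: float = 0.02,
    normalization: str = "tail_unit",
    pbc: bool = True,
) -> RDFProfile:
    """Distance histogram of all reference–target pairs, normalized to g(r).

    ``box_density`` uses ρ_target = N_target / V_box (requires a box);
    ``tail_unit`` needs no box and sets the tail mean to one.
    """
    if normalization not in NORMALIZATIONS:
        raise ConfigurationError(f"unknown RDF normalization {normalization!r}")
    if not (r_max > bin_width > 0):
        raise ConfigurationError("need r_max > bin_width > 0")
    ref = np.asarray(reference, dtype=np.int64)
    tgt = np.asarray(target, dtype=np.int64)
    if ref.size == 0 or tgt.size == 0:
        raise InvalidGroupsError("RDF groups must be nonempty")
    if np.intersect1d(ref, tgt).size:
        raise InvalidGroupsError("RDF groups must be disjoint")
    n_bins = int(round(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    volume = 0.0
    for frame in traj.frames:
        box = frame.box if pbc else None
        _, _, d = pairs_within(frame.coordinates[ref], frame.coordinates[tgt],
                               r_max, box)
        counts += np.histogram(d, bins=edges)[0]
        if frame.box is not None:
            volume += float(np.prod(frame.box))
    centers = (edges[:-1] + edges[1:]) / 2
    shell = 4.0 * np.pi * centers ** 2 * bin_width
    raw = counts / (ref.size * traj.n_frames * shell)
    if normalization == "box_density":
        if volume == 0.0:
            raise ConfigurationError(
                "box_density normalization requires a box on every frame"
            )
        rho = tgt.size / (volume / traj.n_frames)
        g = raw / rho
    else:
        n_tail = max(1, n_bins // 10)
        tail_mean = raw[-n_tail:].mean()
        if tail_mean <= 0:
            raise ConfigurationError(
                "tail_unit normalization: no counts in the last 10% of bins"
            )
        g = raw / tail_mean
    return RDFProfile(
        bin_centers=centers, g=g, counts=counts, normalization=normalization,
        r_max=r_max, bin_width=bin_width, n_reference=int(ref.size),
        n_target=int(tgt.size), n_frames=traj.n_frames,
    )


def pmf_from_rdf(profile: RDFProfile, temperature: float = 310.0) -> PMFProfile:
    """PMF(r) = −RT ln g(r); bins with g = 0 are undefined (NaN)."""
    if temperature <= 0:
        raise ConfigurationError("temperature must be positive")
    with np.errstate(divide="ignore"):
        pmf = np.where(profile.g > 0,
                       -GAS_CONSTANT * temperature * np.log(profile.g), np.nan)
    if not np.any(np.isfinite(pmf)):
        raise ConfigurationError("all g(r) bins are zero; PMF undefined everywhere")
    prof = PMFProfile(bin_centers=profile.bin_centers, pmf=pmf,
                      temperature=temperature, minimum=(np.nan, np.nan),
                      normalization=profile.normalization)
    prof.minimum = pmf_minimum(prof)
    return prof


def pmf_minimum(profile: PMFProfile) -> Tuple[float, float]:
    """(depth kJ/mol, location Å) of the global PMF minimum.

    Ties break toward smaller r (nanargmin returns the first index).
    """
    if not np.any(np.isfinite(profile.pmf)):
        raise ConfigurationError("PMF has no defined bins")
    k = int(np.nanargmin(profile.pmf))
    return float(profile.pmf[k]), float(profile.bin_centers[k])
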