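"""Droplet digital PCR quantification of prey DNA in predator stomachs.

Converts raw droplet counts into mitochondrial 16S gene copies per gram of
stomach content. In ddPCR the template is partitioned into ~20,000 nanolitre
droplets; under Poisson statistics the mean copies per droplet is
``lambda = -ln(1 - p)`` where ``p`` is the positive-droplet fraction, giving a
reaction concentration ``lambda / v_droplet`` in copies per microlitre.

The full normalisation chain per replicate subsample is

    copies/uL reaction  x  (v_reaction / v_template)  x  dilution
        = copies/uL DNA extract
    x  v_elution  = copies per subsample
    /  tissue grams (wet weight corrected for the 1:3 PBS homogenisation)
        = copies per gram stomach content

and the stomach-level value is the arithmetic mean over the (up to five)
replicate subsamples. Visually empty stomachs carry a nominal 0.01 g tissue
weight so a per-gram value remains defined.

QC follows the survey protocol: wells outside 13,000-21,000 accepted droplets
are flagged for repetition; wells with almost no negative droplets are
saturated and their estimate is a lower bound; positive droplets in no-template
or negative controls mark the run as contamination-suspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = [
    "DROPLET_QC_MIN",
    "DROPLET_QC_MAX",
    "SATURATION_MIN_NEGATIVES",
    "DropletReaction",
    "SubsampleRecord",
    "StomachRecord",
    "ConcentrationEstimate",
    "CopyResult",
    "qc_reaction",
    "poisson_concentration",
    "copies_per_g",
    "check_controls",
    "final_primer_concentration_nM",
]

DROPLET_QC_MIN = 13_000     # accepted-droplet window for a valid well
DROPLET_QC_MAX = 21_000
SATURATION_MIN_NEGATIVES = 30   # fewer negatives than this => saturated
EMPTY_STOMACH_TISSUE_G = 0.01   # nominal tissue weight of a visually empty stomach

FLAG_BELOW_DETECTION = "below_detection"
FLAG_SATURATED = "saturated"
FLAG_QC_DROPLET_COUNT = "qc_droplet_count"
FLAG_CONTAMINATION = "contamination_suspect"


@dataclass(frozen=True)
class DropletReaction:
    """One ddPCR well: droplet counts plus dilution and volume metadata."""

    well: str
    stomach: str
    replicate: int
    n_total: int
    n_positive: int
    dilution: float = 1.0
    v_template: float = 5.5     # uL template added to the reaction
    v_reaction: float = 22.0    # uL final reaction volume
    v_droplet: float = 0.85e-3  # uL per droplet (0.85 nL, QX200 convention)

    def __post_init__(self):
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError(
                f"well {self.well}: need 0 <= n_positive <= n_total, "
                f"got {self.n_positive}/{self.n_total}"
            )
        if self.dilution < 1:
            raise ValueError(f"well {self.well}: dilution must be >= 1")
        if min(self.v_template, self.v_reaction, self.v_droplet) <= 0:
            raise ValueError(f"well {self.well}: volumes must be positive")


@dataclass(frozen=True)
class SubsampleRecord:
    """One replicate subsample of a stomach homogenate."""

    stomach: str
    replicate: int
    wet_weight: float          # g, including PBS buffer
    pbs_ratio: float = 3.0     # buffer volumes per volume of content
    v_elution: float = 150.0   # uL DNA eluate (protocol range 100-200)

    def __post_init__(self):
        if self.wet_weight <= 0:
            raise ValueError(f"stomach {self.stomach} rep {self.replicate}: wet_weight must be > 0")
        if self.pbs_ratio < 0:
            raise ValueError("pbs_ratio must be >= 0")

    @property
    def tissue_g(self) -> float:
        """Wet weight corrected to grams of stomach content (PBS removed)."""
        return self.wet_weight / (1.0 + self.pbs_ratio)


@dataclass(frozen=True)
class StomachRecord:
    """Per-fish stomach metadata from the trawl survey."""

    stomach: str
    station: str
    year: int
    fish_weight: float
    content_weight: float
    empty: bool = False

    def __post_init__(self):
        if self.fish_weight <= 0:
            raise ValueError(f"stomach {self.stomach}: fish_weight must be > 0")
        if self.empty and abs(self.content_weight - EMPTY_STOMACH_TISSUE_G) > 1e-12:
            raise ValueError(
                f"stomach {self.stomach}: empty stomachs carry the nominal "
                f"{EMPTY_STOMACH_TISSUE_G} g content weight"
            )
        if self.content_weight <= 0:
            raise ValueError(f"stomach {self.stomach}: content_weight must be > 0")


@dataclass
class ConcentrationEstimate:
    """Poisson estimate of template concentration in one well."""

    copies_per_ul: float
    flags: set = field(default_factory=set)


@dataclass
class CopyResult:
    """Normalised gene copies per gram of stomach content, with QC flags."""

    stomach: str
    copies_per_ul_reaction: float
    copies_per_g: float
    flags: set = field(default_factory=set)
    n_replicates: int = 0
    replicate_values: tuple = ()

    def __post_init__(self):
        if self.copies_per_g < 0:
            raise ValueError("copies_per_g must be >= 0")


def qc_reaction(r: DropletReaction) -> set:
    """Droplet-count QC: outside [13,000, 21,000] accepted droplets fails.

    Returns the (possibly empty) set of flags; boundary values pass.
    """
    if r.n_total < DROPLET_QC_MIN or r.n_total > DROPLET_QC_MAX:
        return {FLAG_QC_DROPLET_COUNT}
    return set()


def poisson_concentration(r: DropletReaction) -> ConcentrationEstimate:
    """Template concentration (copies / uL of reaction) from droplet counts.

    ``lambda = -ln(1 - p)`` copies per droplet, with ``p`` the positive
    fraction; concentration is ``lambda / v_droplet``. All-negative wells
    return 0 with a below-detection flag. Nearly saturated wells (fewer
    than 30 negative droplets) are evaluated at the saturation threshold
    and flagged: the value is a lower bound.
    """
    if r.n_total == 0:
        raise DataError(f"well {r.well}: no accepted droplets")
    flags = qc_reaction(r)
    n_negative = r.n_total - r.n_positive
    if r.n_positive == 0:
        flags.add(FLAG_BELOW_DETECTION)
        return ConcentrationEstimate(0.0, flags)
    if n_negative < SATURATION_MIN_NEGATIVES:
        flags.add(FLAG_SATURATED)
        p = (r.n_total - SATURATION_MIN_NEGATIVES) / r.n_total
    else:
        p = r.n_positive / r.n_total
    lam = -np.log1p(-p)
    return ConcentrationEstimate(float(lam / r.v_droplet), flags)


def normalize_concentration(
    copies_per_ul_reaction: float,
    *,
    dilution: float,
    v_reaction: float = 22.0,
    v_template: float = 5.5,
    v_elution: float = 150.0,
    tissue_g: float,
) -> float:
    """The normalisation chain from reaction concentration to copies per gram.

    reaction copies/uL x (v_reaction / v_template) x dilution = extract
    copies/uL; x v_elution = copies per subsample; / tissue grams = copies
    per gram stomach content.
    """
    if tissue_g <= 0:
        raise DataError("tissue weight must be positive")
    extract_per_ul = copies_per_ul_reaction * (v_reaction / v_template) * dilution
    return extract_per_ul * v_elution / tissue_g


def copies_per_g(
    reactions: list,
    subsamples: list,
    stomach: StomachRecord,
    *,
    below_detection_policy: str = "zero",
) -> CopyResult:
    """Normalise replicate wells of one stomach to gene copies per gram.

    Wells failing droplet-count QC are excluded; at least one replicate must
    survive. Below-detection replicates enter the mean as zero by default
    (``below_detection_policy="exclude"`` drops them instead).
    """
    if below_detection_policy not in ("zero", "exclude"):
        raise ConfigurationError(f"unknown below_detection_policy {below_detection_policy!r}")
    subs = {s.replicate: s for s in subsamples if s.stomach == stomach.stomach}
    mine = [r for r in reactions if r.stomach == stomach.stomach]
    if not mine:
        raise DataError(f"stomach {stomach.stomach}: no reactions supplied")

    usable = [r for r in mine if not qc_reaction(r)]
    if not usable:
        wells = ", ".join(r.well for r in mine)
        raise DataError(
            f"stomach {stomach.stomach}: all replicate wells failed droplet QC ({wells})"
        )

    per_g = []
    per_ul = []
    flags: set = set()
    for r in usable:
        est = poisson_concentration(r)
        flags |= est.flags
        sub = subs.get(r.replicate)
        if sub is None:
            raise DataError(
                f"stomach {stomach.stomach}: no subsample record for replicate {r.replicate}"
            )
        tissue = EMPTY_STOMACH_TISSUE_G if stomach.empty else sub.tissue_g
        if tissue <= 0:
            raise DataError(f"stomach {stomach.stomach}: nonpositive tissue weight")
        value = normalize_concentration(
            est.copies_per_ul, dilution=r.dilution, v_reaction=r.v_reaction,
            v_template=r.v_template, v_elution=sub.v_elution, tissue_g=tissue,
        )
        if FLAG_BELOW_DETECTION in est.flags and below_detection_policy == "exclude":
            continue
        per_ul.append(est.copies_per_ul)
        per_g.append(value)

    if not per_g:  # every replicate excluded as below detection
        flags.add(FLAG_BELOW_DETECTION)
        return CopyResult(stomach.stomach, 0.0, 0.0, flags, 0, ())

    mean_g = float(np.mean(per_g))
    if mean_g > 0:
        flags.discard(FLAG_BELOW_DETECTION)
    return CopyResult(
        stomach=stomach.stomach,
        copies_per_ul_reaction=float(np.mean(per_ul)),
        copies_per_g=mean_g,
        flags=flags,
        n_replicates=len(per_g),
        replicate_values=tuple(per_g),
    )


def check_controls(wells: dict, *, tolerance: int = 2) -> dict:
    """Validate the control wells of a ddPCR run.

    ``wells`` maps a role in {"ntc", "positive", "negative", "blank",
    "sample"} to a list of :class:`DropletReaction`. Positive droplets above
    ``tolerance`` in any NTC, negative control or blank mark the run as
    contamination-suspect; a positive control without positives voids it.
    """
    roles = {k: list(v) for k, v in wells.items()}
    if not roles.get("ntc"):
        raise ConfigurationError("run is missing a no-template control (NTC)")
    if not roles.get("positive"):
        raise ConfigurationError("run is missing a positive control")

    contaminated = []
    for role in ("ntc", "negative", "blank"):
        for r in roles.get(role, []):
            if r.n_positive > tolerance:
                contaminated.append((role, r.well, r.n_positive))
    positive_ok = all(r.n_positive > 0 for r in roles["positive"])
    return {
        "valid": positive_ok,
        "contamination_suspect": bool(contaminated),
        "contaminated_wells": contaminated,
        "flags": ({FLAG_CONTAMINATION} if contaminated else set()),
    }


def final_primer_concentration_nM(amount_pmol: float, reaction_volume_ul: float) -> float:
    """Final primer concentration in nM from pmol added to a reaction volume.

    pmol / uL is micromolar, so the nanomolar value is scaled by 1000
    (e.g. 2.2 pmol in 22 uL is 100 nM).
    """
    if reaction_volume_ul <= 0:
        raise ValueError("reaction volume must be positive")
    return amount_pmol / reaction_volume_ul * 1000.0
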