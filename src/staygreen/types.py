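"""Core containers shared across the pipeline.

The central in-memory objects are deliberately thin wrappers around pandas
DataFrames so that every stage can be driven from CSV files: a
:class:`GenotypeMatrix` (cultivars x markers allele doses plus a marker map),
a :class:`TrialDesign` describing the split-plot field layout, and the small
result records (:class:`VarianceComponents`, :class:`HaplotypeCall`).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

# Nitrogen levels are identified by their dose in kg N/ha; the lowest dose is
# the "low N" treatment throughout.
DEFAULT_N_LEVELS: tuple[int, ...] = (81, 110, 220)

DEFAULT_IMAGING_DATES: tuple[_dt.date, ...] = (
    _dt.date(2020, 5, 27),
    _dt.date(2020, 6, 9),
    _dt.date(2020, 6, 24),
    _dt.date(2020, 7, 7),
)

#: The two dates spanning the central senescence phase used to pool genotype
#: effects and define the stay-green cultivar set.
CENTRAL_DATES: tuple[_dt.date, ...] = (_dt.date(2020, 6, 9), _dt.date(2020, 6, 24))


@dataclass(frozen=True)
class TrialDesign:
    """Split-plot field trial: N levels as main plots, cultivars in blocks.

    Every cultivar appears exactly once per block per N level; imaging dates
    must be strictly increasing.
    """

    n_cultivars: int = 221
    n_levels: tuple[int, ...] = DEFAULT_N_LEVELS
    n_blocks: int = 2
    imaging_dates: tuple[_dt.date, ...] = DEFAULT_IMAGING_DATES
    plot_width: float = 3.0   # m
    plot_length: float = 7.0  # m

    def __post_init__(self):
        if self.n_cultivars <= 0 or self.n_blocks <= 0 or len(self.n_levels) == 0:
            raise ConfigurationError("trial design counts must be positive")
        dates = list(self.imaging_dates)
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ConfigurationError("imaging dates must be strictly increasing")
        if self.plot_width <= 0 or self.plot_length <= 0:
            raise ConfigurationError("plot geometry must be positive")

    @property
    def low_n(self) -> int:
        return min(self.n_levels)

    @property
    def n_plots(self) -> int:
        return self.n_cultivars * len(self.n_levels) * self.n_blocks


@dataclass(frozen=True)
class CausalLocus:
    """A planted causal locus acting on senescence onset.

    ``onset_shift_gdd`` is the delay of the senescence inflection (in GDD)
    conferred per favourable-allele dose fraction (homozygous carrier = full
    shift); positive shifts delay senescence, i.e. lower PSRI.
    ``n_specificity`` is ``"all"`` (acts at every N level) or ``"low-only"``
    (acts only at the lowest N dose).  ``favourable`` names which allele is
    favourable (``"major"`` or ``"minor"``).
    """

    name: str
    chrom: str
    pos: int
    maf: float
    onset_shift_gdd: float
    n_specificity: str = "all"
    favourable: str = "minor"
    #: optional minor-allele frequency by decade (German cultivars), modelling
    #: introduction and indirect selection of the allele over breeding history
    maf_by_decade: Mapping[int, float] | None = None

    def __post_init__(self):
        if not (0.0 < self.maf < 0.5):
            raise ConfigurationError(f"locus {self.name}: MAF must be in (0, 0.5)")
        if not np.isfinite(self.onset_shift_gdd):
            raise ConfigurationError(f"locus {self.name}: effect size must be finite")
        if self.n_specificity not in ("all", "low-only"):
            raise ConfigurationError(
                f"locus {self.name}: n_specificity must be 'all' or 'low-only'"
            )
        if self.favourable not in ("major", "minor"):
            raise ConfigurationError(
                f"locus {self.name}: favourable must be 'major' or 'minor'"
            )


@dataclass(frozen=True)
class CausalSpec:
    """Set of planted causal loci plus LD-block geometry."""

    loci: tuple[CausalLocus, ...]
    ld_block_width: int = 2_000_000  # bp
    markers_per_block: int = 8
    block_r2_target: float = 0.85

    @staticmethod
    def default() -> "CausalSpec":
        """Three-locus architecture mirroring the study conditions.

        Two favourable-major loci acting across N levels and one
        favourable-minor locus specific to low N whose allele frequency rises
        over recent decades.  The first locus' effect is calibrated so that
        its by-construction PVE on pooled genotype effects is ~25%.
        """
        return CausalSpec(
            loci=(
                CausalLocus("L2D", "2D", 23_400_000, maf=0.10,
                            onset_shift_gdd=160.0, n_specificity="all",
                            favourable="major"),
                CausalLocus("L4B", "4B", 15_300_000, maf=0.10,
                            onset_shift_gdd=105.0, n_specificity="all",
                            favourable="major"),
                CausalLocus("L3A", "3A", 83_700_000, maf=0.10,
                            onset_shift_gdd=140.0, n_specificity="low-only",
                            favourable="minor",
                            maf_by_decade={1960: 0.0, 1970: 0.0, 1980: 0.05,
                                           1990: 0.08, 2000: 0.12, 2010: 0.24,
                                           2020: 0.24}),
            ),
        )


@dataclass(frozen=True)
class SenescenceParams:
    """Four-parameter logistic senescence trajectory family in thermal time.

    PSRI rises from ``baseline`` to ``asymptote`` with inflection at
    ``onset_gdd`` and slope ``rate`` per GDD.  ``n_onset_shift`` moves the
    inflection by N level (low N senesces earlier -> negative shift).  An
    optional mid-season ``plateau`` of given GDD length freezes the
    trajectory just after onset, mimicking the temporary stagnation some
    cultivars show between the central dates.
    """

    onset_gdd: float = 865.0
    onset_sd: float = 55.0
    rate: float = 0.013      # per GDD
    rate_sd: float = 0.002
    baseline: float = 0.15
    asymptote: float = 1.2
    noise_sd: float = 0.03
    n_onset_shift: Mapping[int, float] = field(
        default_factory=lambda: {81: -85.0, 110: -35.0, 220: 0.0})
    plateau_gdd: float = 0.0
    #: target plot-level PSRI-AUC vs grain-yield correlations per N level,
    #: strongest (most negative) at low N
    yield_corr: Mapping[int, float] = field(
        default_factory=lambda: {81: -0.80, 110: -0.70, 220: -0.68})

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigurationError("senescence rate must be >= 0")
        if self.asymptote < self.baseline:
            raise ConfigurationError("asymptote must be >= baseline")


class GenotypeMatrix:
    """Cultivars x markers allele-dose matrix with marker map and metadata.

    Doses count copies of the **minor** allele (0/1/2, NaN = missing); the
    panel is treated as fully inbred by default so observed doses are 0/2.

    Parameters
    ----------
    doses : DataFrame, index = cultivar ids, columns = marker ids.
    marker_map : DataFrame indexed by marker id with columns
        ``chrom``, ``pos`` (1-based bp), ``major``, ``minor`` (allele bases).
    metadata : optional DataFrame indexed by cultivar id with columns such as
        ``decade`` and ``origin`` (population-structure groups).
    """

    def __init__(self, doses: pd.DataFrame, marker_map: pd.DataFrame,
                 metadata: pd.DataFrame | None = None):
        if not doses.columns.equals(marker_map.index):
            marker_map = marker_map.loc[doses.columns]
        self.doses = doses
        self.marker_map = marker_map
        self.metadata = metadata

    # -- basic accessors -------------------------------------------------
    @property
    def cultivars(self) -> pd.Index:
        return self.doses.index

    @property
    def markers(self) -> pd.Index:
        return self.doses.columns

    @property
    def n_cultivars(self) -> int:
        return self.doses.shape[0]

    @property
    def n_markers(self) -> int:
        return self.doses.shape[1]

    def maf(self) -> pd.Series:
        """Per-marker minor allele frequency among observed calls."""
        freq = self.doses.mean(axis=0, skipna=True) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def minor_allele_frequency_raw(self) -> pd.Series:
        """Frequency of the allele counted by the dose coding (unfolded)."""
        return self.doses.mean(axis=0, skipna=True) / 2.0

    def missing_rate(self) -> pd.Series:
        return self.doses.isna().mean(axis=0)

    def subset_markers(self, markers: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.doses[list(markers)],
                              self.marker_map.loc[list(markers)], self.metadata)

    def subset_cultivars(self, cultivars: Sequence[str]) -> "GenotypeMatrix":
        return GenotypeMatrix(self.doses.loc[list(cultivars)], self.marker_map,
                              None if self.metadata is None
                              else self.metadata.loc[list(cultivars)])

    # -- HapMap-style CSV round trip ------------------------------------
    def to_hapmap_csv(self, path) -> None:
        """Write rs/chrom/pos/alleles columns followed by one column per cultivar."""
        out = pd.DataFrame({
            "rs": self.markers,
            "chrom": self.marker_map["chrom"].values,
            "pos": self.marker_map["pos"].values,
            "alleles": (self.marker_map["major"] + "/" + self.marker_map["minor"]).values,
        })
        body = self.doses.T
        body.columns = [str(c) for c in body.columns]
        out = pd.concat([out.set_index(self.markers), body], axis=1)
        out.to_csv(path, index=False)

    @staticmethod
    def from_hapmap_csv(path, metadata: pd.DataFrame | None = None) -> "GenotypeMatrix":
        raw = pd.read_csv(path)
        meta_cols = ["rs", "chrom", "pos", "alleles"]
        alleles = raw["alleles"].str.split("/", expand=True)
        marker_map = pd.DataFrame({
            "chrom": raw["chrom"].astype(str).values,
            "pos": raw["pos"].astype(int).values,
            "major": alleles[0].values,
            "minor": alleles[1].values,
        }, index=pd.Index(raw["rs"], name="marker"))
        doses = raw.drop(columns=meta_cols).T
        doses.columns = marker_map.index
        doses.index.name = "cultivar"
        return GenotypeMatrix(doses.astype(float), marker_map, metadata)

    @staticmethod
    def from_vcf(path, metadata: pd.DataFrame | None = None) -> "GenotypeMatrix":
        """Minimal VCF reader: GT field -> minor-allele dose (./.-> NaN)."""
        rows, markers, chroms, poss, refs, alts = [], [], [], [], [], []
        samples: list[str] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("##"):
                    continue
                parts = line.rstrip("\n").split("\t")
                if line.startswith("#CHROM"):
                    samples = parts[9:]
                    continue
                chrom, pos, mid, ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
                fmt = parts[8].split(":")
                gt_i = fmt.index("GT")
                doses = []
                for s in parts[9:]:
                    gt = s.split(":")[gt_i].replace("|", "/")
                    if "." in gt:
                        doses.append(np.nan)
                    else:
                        doses.append(float(sum(int(a) for a in gt.split("/"))))
                markers.append(mid)
                chroms.append(chrom)
                poss.append(int(pos))
                refs.append(ref)
                alts.append(alt)
                rows.append(doses)
        doses = pd.DataFrame(np.asarray(rows, dtype=float).T,
                             index=pd.Index(samples, name="cultivar"),
                             columns=pd.Index(markers, name="marker"))
        # ALT is taken as the counted allele; fold major/minor by frequency
        alt_freq = doses.mean(axis=0, skipna=True) / 2.0
        major = np.where(alt_freq <= 0.5, refs, alts)
        minor = np.where(alt_freq <= 0.5, alts, refs)
        folded = doses.copy()
        flip = alt_freq.index[alt_freq > 0.5]
        folded[flip] = 2.0 - folded[flip]
        marker_map = pd.DataFrame({"chrom": chroms, "pos": poss,
                                   "major": major, "minor": minor},
                                  index=doses.columns)
        return GenotypeMatrix(folded, marker_map, metadata)


@dataclass(frozen=True)
class VarianceComponents:
    """Cultivar, cultivar-x-N and residual variance with design counts.

    ``n`` is the number of N levels, ``r`` the number of replications
    (blocks x replicates per block) entering the reliability denominator.
    ``truncated`` flags a negative method-of-moments solution set to zero.
    """

    v_c: float
    v_cxn: float
    v_r: float
    n: int
    r: int
    truncated: bool = False

    def __post_init__(self):
        if min(self.v_c, self.v_cxn, self.v_r) < 0:
            raise ConfigurationError("variance components must be >= 0")
        if self.n < 1 or self.r < 1:
            raise ConfigurationError("design counts must be >= 1")


@dataclass
class HaplotypeCall:
    """Haplotype clustering result around one focal GWAS marker."""

    focal: str
    members: tuple[str, ...]
    span_mbp: tuple[float, float]
    assignments: pd.Series        # cultivar -> cluster label (int)
    codes: dict[int, str] = field(default_factory=dict)   # cluster -> e.g. "MG", "MGv"
    sizes: dict[int, int] = field(default_factory=dict)
    favourable: dict[int, bool] = field(default_factory=dict)
    tie_flag: bool = False

    def code_of(self, cultivar) -> str:
        return self.codes[int(self.assignments.loc[cultivar])]

    def favourable_cultivars(self) -> pd.Index:
        fav = {c for c, f in self.favourable.items() if f}
        return self.assignments.index[self.assignments.isin(fav)]


def as_date(x) -> _dt.date:
    if isinstance(x, _dt.date):
        return x
    return _dt.date.fromisoformat(str(x))
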