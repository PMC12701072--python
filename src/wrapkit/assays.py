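"""Quantitation of the supporting biophysical assays.

Covers molecular-mass arithmetic for stoichiometry assignment (SEC-MALS),
Shine–Dalgarno scanning to rank candidate start codons, densitometric sizing
of nuclease-protection ladders against a marker lane, tethered-particle-
motion (TPM) logistic fits, and binding-isotherm fits.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .structio import SequenceRecord

__all__ = [
    "MassResult",
    "LaneProfile",
    "TpmFit",
    "IsothermFit",
    "SdHit",
    "protein_mass",
    "nucleic_mass",
    "duplex_mass",
    "complex_mass",
    "sd_scan",
    "ladder_sizing",
    "tpm_logistic_fit",
    "isotherm_fit",
    "AMINO_ACID_MASSES",
    "NUCLEOTIDE_MASSES",
    "GENERULER_ULTRA_LOW_BP",
]

WATER = 18.0153
HPO3 = 79.9799  # mass removed when a 5'-phosphate is replaced by 5'-OH

# average (not monoisotopic) residue masses, Da
AMINO_ACID_MASSES = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
# deoxynucleotide 5'-monophosphate residue masses (internal), Da
NUCLEOTIDE_MASSES = {"A": 313.2090, "C": 289.1842, "G": 329.2084, "T": 304.1962}

GENERULER_ULTRA_LOW_BP = (10, 15, 20, 25, 35, 50, 75, 100, 150, 200, 300)


@dataclasses.dataclass(frozen=True)
class MassResult:
    mass: float  # Da
    composition: dict

    @property
    def kda(self) -> float:
        """Mass in kDa rounded to 1 decimal."""
        return round(self.mass / 1000.0, 1)

    def percent_deviation(self, measured_da: float) -> float:
        return 100.0 * (measured_da - self.mass) / self.mass


def protein_mass(seq: SequenceRecord | str,
                 remove_n_terminal_met: bool = False) -> MassResult:
    """Average molecular mass of a peptide.

    Sum of residue masses plus one water (the peptide-bond convention
    Σ residues − (n−1)·18.0153 applied to free amino-acid masses).
    """
    residues = seq.residues if isinstance(seq, SequenceRecord) else seq
    residues = residues.upper()
    if remove_n_terminal_met and residues.startswith("M"):
        residues = residues[1:]
    bad = set(residues) - set(AMINO_ACID_MASSES)
    if bad:
        raise ValueError(f"non-standard amino-acid letters: {sorted(bad)}")
    if not residues:
        raise ValueError("empty sequence")
    mass = sum(AMINO_ACID_MASSES[a] for a in residues) + WATER
    return MassResult(mass, dict(Counter(residues)))


def nucleic_mass(seq: SequenceRecord | str, strands: int = 1,
                 five_prime: str = "OH") -> MassResult:
    """Average mass of a DNA single strand or duplex.

    ``five_prime`` is "OH" (synthesized oligos, default) or "phosphate";
    the difference is one HPO₃ (≈ 80 Da) per strand.  For ``strands=2`` the
    complementary strand is generated and both are summed.
    """
    residues = (seq.residues if isinstance(seq, SequenceRecord) else seq).upper()
    bad = set(residues) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT letters: {sorted(bad)}")
    if not residues:
        raise ValueError("empty sequence")
    if strands not in (1, 2):
        raise ValueError("strands must be 1 or 2")
    if five_prime not in ("OH", "phosphate"):
        raise ValueError("five_prime must be 'OH' or 'phosphate'")

    def strand_mass(s: str) -> float:
        m = sum(NUCLEOTIDE_MASSES[b] for b in s) + WATER
        if five_prime == "OH":
            m -= HPO3
        return m

    comp = Counter(residues)
    mass = strand_mass(residues)
    if strands == 2:
        comp_map = {"A": "T", "T": "A", "C": "G", "G": "C"}
        rc = "".join(comp_map[b] for b in reversed(residues))
        mass += strand_mass(rc)
        comp += Counter(rc)
    return MassResult(mass, dict(comp))


def duplex_mass(seq: SequenceRecord | str, five_prime: str = "OH") -> MassResult:
    return nucleic_mass(seq, strands=2, five_prime=five_prime)


def complex_mass(parts: list[MassResult], stoichiometry: list[int]) -> MassResult:
    """Theoretical mass of a stoichiometric complex, Σ count × part mass."""
    if len(parts) != len(stoichiometry):
        raise ValueError("parts and stoichiometry lengths differ")
    if not parts or all(c == 0 for c in stoichiometry):
        warnings.warn("empty stoichiometry; mass is 0")
        return MassResult(0.0, {})
    total = 0.0
    comp: Counter = Counter()
    for part, count in zip(parts, stoichiometry):
        if count < 0:
            raise ValueError("stoichiometric counts must be non-negative")
        total += count * part.mass
        for k, v in part.composition.items():
            comp[k] += count * v
    return MassResult(total, dict(comp))


# ---------------------------------------------------------------------------
# Shine–Dalgarno scan
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SdHit:
    start: int          # 1-based position of the candidate start codon
    codon: str
    score: int          # longest contiguous match to the SD motif
    spacing: int        # nt between motif 3' end and the start codon
    strong: bool


def _best_match(window: str, motif: str) -> int:
    """Longest contiguous run of positional matches."""
    best = run = 0
    for a, b in zip(window, motif):
        run = run + 1 if a == b else 0
        best = max(best, run)
    return best


def sd_scan(context: SequenceRecord | str, starts: list[int],
            motif: str = "AGGAGG", spacing_range: tuple[int, int] = (4, 14),
            strong_score: int = 5) -> list[SdHit]:
    """Scan upstream of candidate start codons for a Shine–Dalgarno motif.

    For each 1-based start position the anti-SD complement (default AGGAGG)
    is slid over spacings of 4–14 nt upstream; the score is the longest
    contiguous match at the best spacing.  Hits are returned ranked by score
    (descending), which supports choosing between alternative start codons.
    Non-ATG/GTG/TTG codons are scored but flagged with a warning.
    """
    seq = (context.residues if isinstance(context, SequenceRecord)
           else context).upper()
    lo, hi = spacing_range
    out = []
    for start in starts:
        p = start - 1
        if p < 20:
            raise ValueError(f"start {start} has fewer than 20 nt of upstream "
                             "context")
        codon = seq[p:p + 3]
        if codon not in ("ATG", "GTG", "TTG"):
            warnings.warn(f"start {start}: codon {codon} is not ATG/GTG/TTG")
        best_score, best_spacing = 0, lo
        for s in range(lo, hi + 1):
            end = p - s
            beg = end - len(motif)
            if beg < 0:
                continue
            score = _best_match(seq[beg:end], motif)
            if score > best_score:
                best_score, best_spacing = score, s
        out.append(SdHit(start, codon, best_score, best_spacing,
                         best_score >= strong_score))
    out.sort(key=lambda h: (-h.score, h.start))
    return out


# ---------------------------------------------------------------------------
# ladder densitometry
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LaneProfile:
    """A densitometric lane: migration positions and intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.shape != self.intensities.shape:
            raise ValueError("positions/intensities length mismatch")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    def detect_peaks(self) -> np.ndarray:
        """Peak migration positions above a median + 3×MAD noise floor."""
        y = self.intensities
        med = np.median(y)
        mad = np.median(np.abs(y - med))
        floor = med + 3.0 * 1.4826 * mad
        prominence = max(floor, 0.05 * y.max())
        idx, _ = find_peaks(y, height=max(floor, 1e-12), prominence=prominence)
        # sub-pixel refinement: parabola through the vertex and neighbours
        out = []
        for i in idx:
            if 0 < i < len(y) - 1:
                denom = y[i - 1] - 2 * y[i] + y[i + 1]
                shift = 0.5 * (y[i - 1] - y[i + 1]) / denom if denom != 0 else 0.0
                dx = self.positions[min(i + 1, len(y) - 1)] - self.positions[i]
                out.append(self.positions[i] + np.clip(shift, -0.5, 0.5) * dx)
            else:
                out.append(self.positions[i])
        return np.asarray(out, dtype=float)


@dataclasses.dataclass(frozen=True)
class SizedFragment:
    size_bp: float
    uncertainty_bp: float
    position: float
    extrapolated: bool


def ladder_sizing(sample: LaneProfile, marker: LaneProfile,
                  marker_sizes_bp: list[float]) -> list[SizedFragment]:
    """Size sample-lane bands against a marker lane.

    The calibration is a linear fit of log10(size) against marker-band
    migration (strictly monotone over the marker range); sample peaks are
    interpolated through it, with uncertainties propagated from calibration
    residuals.  Peaks migrating outside the marker range are flagged as
    extrapolated rather than silently sized.
    """
    marker_pos = marker.detect_peaks()
    sizes = np.sort(np.asarray(marker_sizes_bp, dtype=float))[::-1]
    if len(marker_pos) < 3:
        raise ValueError("need at least 3 detected marker bands")
    if len(marker_pos) != len(sizes):
        raise ValueError(
            f"detected {len(marker_pos)} marker bands but {len(sizes)} sizes "
            "given")
    # migration increases as size decreases: pair in order
    logsize = np.log10(sizes)
    coeff = np.polyfit(marker_pos, logsize, 1)
    fitted = np.polyval(coeff, marker_pos)
    if not (np.all(np.diff(fitted) < 0) or np.all(np.diff(fitted) > 0)):
        raise ValueError("calibration is not monotone over the marker range")
    resid_sd = float(np.sqrt(np.mean((fitted - logsize) ** 2)))
    out = []
    for pos in sample.detect_peaks():
        ls = float(np.polyval(coeff, pos))
        size = 10.0 ** ls
        unc = np.log(10) * size * resid_sd
        extrapolated = not (marker_pos.min() <= pos <= marker_pos.max())
        out.append(SizedFragment(size, float(unc), float(pos), extrapolated))
    return out


# ---------------------------------------------------------------------------
# TPM logistic fit
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TpmFit:
    rms0: float       # upper plateau, nm
    rms_min: float    # lower plateau, nm
    c_half: float     # midpoint concentration, nM
    slope: float
    saturation_nM: float  # concentration at 95% of the total RMS drop
    converged: bool
    message: str
    covariance: np.ndarray | None = None

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(conc > 0, (conc / self.c_half) ** self.slope, 0.0)
        return self.rms_min + (self.rms0 - self.rms_min) / (1.0 + ratio)


def _logistic(c, rms0, rms_min, c_half, k):
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / c_half) ** k, 0.0)
    return rms_min + (rms0 - rms_min) / (1.0 + ratio)


def tpm_logistic_fit(conc_nM, rms_nm, replicate_sd=None) -> TpmFit:
    """Fit bead-excursion RMS vs protein concentration to a 4-parameter
    logistic, RMS(c) = RMSmin + (RMS0 − RMSmin)/(1 + (c/c½)^k).

    Saturation is reported as the concentration at 95% of the total drop.
    Degenerate (flat) data return a flagged, non-converged fit instead of
    raising.
    """
    conc = np.asarray(conc_nM, dtype=float)
    rms = np.asarray(rms_nm, dtype=float)
    if conc.size < 4:
        raise ValueError("need at least 4 concentrations")
    if not np.any(conc <= 0.05 * conc.max()):
        raise ValueError("need a zero or near-zero concentration point")
    if np.ptp(rms) < 1e-9:
        return TpmFit(float(rms[0]), float(rms[0]), float("nan"), float("nan"),
                      float("nan"), False, "degenerate fit: constant RMS")
    sigma = None
    if replicate_sd is not None:
        sigma = np.asarray(replicate_sd, dtype=float)
        sigma = np.where(sigma > 0, sigma, np.nanmean(sigma[sigma > 0])
                         if np.any(sigma > 0) else 1.0)
    pos = conc[conc > 0]
    p0 = [float(rms.max()), float(rms.min()),
          float(np.sqrt(pos.min() * pos.max())), 1.5]
    try:
        popt, pcov = curve_fit(_logistic, conc, rms, p0=p0, sigma=sigma,
                               maxfev=20000,
                               bounds=([0, 0, 1e-9, 0.05],
                                       [np.inf, np.inf, np.inf, 20.0]))
        converged = True
        message = "ok"
    except RuntimeError as exc:
        popt, pcov = p0, None
        converged = False
        message = f"fit did not converge: {exc}"
    rms0, rms_min, c_half, k = (float(v) for v in popt)
    saturation = c_half * 19.0 ** (1.0 / k)
    return TpmFit(rms0, rms_min, c_half, k, float(saturation), converged,
                  message, pcov if converged else None)


# ---------------------------------------------------------------------------
# binding isotherm
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IsothermFit:
    kd: float
    hill: float           # 1.0 for the 1:1 model
    amplitude: float
    baseline: float
    model: str            # "one_site" | "hill" | "no_binding"
    aic: dict
    kd_is_bound: bool
    probe_conc: float

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        if self.model == "no_binding":
            return np.full_like(conc, self.baseline)
        if self.model == "one_site":
            fb = _one_site(conc, self.kd, self.probe_conc)
        else:
            fb = conc ** self.hill / (self.kd ** self.hill + conc ** self.hill)
        return self.baseline + self.amplitude * fb


def _one_site(conc, kd, probe):
    """Fraction of probe bound, ligand-depletion-aware (quadratic)."""
    b = probe + conc + kd
    return (b - np.sqrt(b * b - 4.0 * probe * conc)) / (2.0 * probe)


def _aic(resid, n_params, n):
    rss = float(np.sum(resid ** 2))
    return n * np.log(max(rss, 1e-300) / n) + 2 * n_params


def isotherm_fit(conc, response, probe_conc: float | None = None) -> IsothermFit:
    """Fit a binding isotherm with 1:1 (depletion-aware) and Hill models.

    ``probe_conc`` is the labelled-species concentration in the same units
    as ``conc``; when omitted a trace-probe limit (hyperbolic 1:1) is used.
    The model with the lower AIC is selected.  A titration spanning fewer
    than 2 decades only bounds Kd and is flagged; a flat response returns a
    no-binding verdict.
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.size < 5:
        raise ValueError("need at least 5 concentrations")
    pos = conc[conc > 0]
    span_decades = np.log10(pos.max() / pos.min())
    if np.ptp(resp) < 1e-9 * max(1.0, abs(resp).max()):
        return IsothermFit(float("inf"), 1.0, 0.0, float(resp[0]),
                           "no_binding", {}, True, probe_conc or 0.0)
    probe = probe_conc if probe_conc is not None else 1e-9 * pos.min()

    def f_one(c, kd, amp, base):
        return base + amp * _one_site(c, kd, probe)

    def f_hill(c, kd, n, amp, base):
        with np.errstate(divide="ignore", invalid="ignore"):
            fb = np.where(c > 0, c ** n / (kd ** n + c ** n), 0.0)
        return base + amp * fb

    kd0 = float(np.sqrt(pos.min() * pos.max()))
    amp0 = float(resp.max() - resp.min())
    base0 = float(resp.min())
    fits = {}
    try:
        p1, _ = curve_fit(f_one, conc, resp, p0=[kd0, amp0, base0],
                          maxfev=20000, bounds=([1e-12, -np.inf, -np.inf],
                                                [np.inf, np.inf, np.inf]))
        fits["one_site"] = (p1, _aic(resp - f_one(conc, *p1), 3, conc.size))
    except RuntimeError:
        pass
    try:
        p2, _ = curve_fit(f_hill, conc, resp, p0=[kd0, 1.5, amp0, base0],
                          maxfev=20000,
                          bounds=([1e-12, 0.2, -np.inf, -np.inf],
                                  [np.inf, 10.0, np.inf, np.inf]))
        fits["hill"] = (p2, _aic(resp - f_hill(conc, *p2), 4, conc.size))
    except RuntimeError:
        pass
    if not fits:
        raise RuntimeError("neither binding model converged")
    best = min(fits, key=lambda k: fits[k][1])
    params = fits[best][0]
    aic = {k: float(v[1]) for k, v in fits.items()}
    bound_only = span_decades < 2.0
    if bound_only:
        warnings.warn("titration spans fewer than 2 decades; Kd is a bound, "
                      "not an estimate")
    if best == "one_site":
        kd, amp, base = (float(v) for v in params)
        return IsothermFit(kd, 1.0, amp, base, "one_site", aic, bound_only,
                           probe)
    kd, n, amp, base = (float(v) for v in params)
    return IsothermFit(kd, n, amp, base, "hill", aic, bound_only, probe)
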