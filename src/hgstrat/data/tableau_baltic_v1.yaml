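# Chemical-equilibrium tableau for Hg(II)/MeHg speciation in brackish,
# sulfidic water (Baltic-type conditions: pH 7.3, 90 mM Cl-).
#
# Transcription notes
# -------------------
# Constants are this package's transcription of the published
# Hg/MeHg-sulfide-thiol-chloride equilibrium model family
# (Skyllberg / Drott / Liem-Nguyen lineage), conditioned to circumneutral
# brackish water with activity coefficients of unity.  Anchors:
#   * Hg(SH)2 log beta 37.71 (literature);
#   * the two deprotonation steps of the dissolved Hg-sulfide triplet are
#     set at pKa1 = 6.37 and pKa2 = 8.71, the values implied by the
#     86.5 / 10.1 / 3.4 % (HgS2H- / Hg(SH)2 / HgS2^2-) distribution of the
#     dissolved pool at pH 7.3 that the source model reports;
#   * metacinnabar HgS(s) logK 36.60 and Hg(SR)2 log beta 41.2, within
#     literature ranges, giving thiol -> HgS(s) -> dissolved-sulfide
#     dominance boundaries near 0.003 and 0.25 uM H2S for picomolar Hg(II)
#     and ~4 mg C/L DOC, the regime structure the source model reports.
# Deviations from any specific published table are possible; this file is
# the versioned source of truth for the package.
#
# Conventions
# -----------
# Species are formed from components by mass action:
#   log10 c_species = logK + sum_j nu_j * log10 a_j
# with a_j the free concentration (activity) of component j.  Stoichiometry
# is the signed "nu" mapping; omitted components have nu = 0.  H2O has fixed
# activity 1; H+ and Cl- are fixed-free components (pH 7.3, 90 mM) unless
# overridden at solve time.

version: baltic-v1

components:
  - name: Hg2        # Hg2+
    mode: total
  - name: MeHg       # CH3Hg+
    mode: total
  - name: H          # H+, fixed by pH
    mode: fixed
    fixed_free_value: 5.0119e-8   # pH 7.3
  - name: Cl         # Cl-, fixed free
    mode: fixed
    fixed_free_value: 0.090
  - name: HS         # HS-, carries total S(-II)
    mode: total
  - name: RS         # DOM thiolate RS-, carries total thiol sites
    mode: total
  - name: H2O        # fixed activity 1
    mode: fixed
    fixed_free_value: 1.0

species:
  # -- sulfide / thiol / water side reactions --
  - {name: H2S,       stoichiometry: {HS: 1, H: 1},            logK: 7.02}
  - {name: S2-,       stoichiometry: {HS: 1, H: -1},           logK: -17.40}
  - {name: OH-,       stoichiometry: {H2O: 1, H: -1},          logK: -13.997}
  - {name: RSH,       stoichiometry: {RS: 1, H: 1},            logK: 9.96}
  # -- dissolved Hg(II)-sulfide triplet --
  - {name: Hg(SH)2,   stoichiometry: {Hg2: 1, HS: 2},          logK: 37.71}
  - {name: HgS2H-,    stoichiometry: {Hg2: 1, HS: 2, H: -1},   logK: 31.34}
  - {name: HgS2-2,    stoichiometry: {Hg2: 1, HS: 2, H: -2},   logK: 22.63}
  # -- solid phase --
  - {name: HgS(s),    stoichiometry: {Hg2: 1, HS: 1, H: -1},   logK: 36.60, phase: solid}
  # -- Hg(II)-thiol --
  - {name: Hg(SR)2,   stoichiometry: {Hg2: 1, RS: 2},          logK: 41.20}
  - {name: HgSR+,     stoichiometry: {Hg2: 1, RS: 1},          logK: 30.40}
  # -- Hg(II)-chloride / hydroxide --
  - {name: HgCl+,     stoichiometry: {Hg2: 1, Cl: 1},          logK: 7.31}
  - {name: HgCl2,     stoichiometry: {Hg2: 1, Cl: 2},          logK: 14.00}
  - {name: HgCl3-,    stoichiometry: {Hg2: 1, Cl: 3},          logK: 14.93}
  - {name: HgCl4-2,   stoichiometry: {Hg2: 1, Cl: 4},          logK: 15.53}
  - {name: HgOHCl,    stoichiometry: {Hg2: 1, Cl: 1, H2O: 1, H: -1}, logK: 4.27}
  - {name: HgOH+,     stoichiometry: {Hg2: 1, H2O: 1, H: -1},  logK: -3.40}
  - {name: Hg(OH)2,   stoichiometry: {Hg2: 1, H2O: 2, H: -2},  logK: -5.98}
  - {name: Hg(OH)3-,  stoichiometry: {Hg2: 1, H2O: 3, H: -3},  logK: -21.10}
  # -- MeHg --
  - {name: MeHgSH,    stoichiometry: {MeHg: 1, HS: 1},         logK: 14.50}
  - {name: MeHgS-,    stoichiometry: {MeHg: 1, HS: 1, H: -1},  logK: 7.50}
  - {name: MeHgSR,    stoichiometry: {MeHg: 1, RS: 1},         logK: 16.50}
  - {name: MeHgCl,    stoichiometry: {MeHg: 1, Cl: 1},         logK: 5.25}
  - {name: MeHgOH,    stoichiometry: {MeHg: 1, H2O: 1, H: -1}, logK: -4.63}
  - {name: (MeHg)2S,  stoichiometry: {MeHg: 2, HS: 1, H: -1},  logK: 16.30}
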