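"""Packaged key-comparison datasets used throughout the tests and examples.

Eight historical interlaboratory datasets, stored to full printed precision:
five CCQM key comparisons (tin in tomato paste, zinc and nickel in bovine
liver, lead in lead-free solder, lead in wine), two radionuclide studies
(equivalent activity of Zn-65 at the SIR, half-life of Sr-90), and one CCEM
microwave power-sensor comparison.  Inclusion flags mirror each final
report's substantive selections; where an expanded uncertainty U and
coverage factor k were reported instead of u, the stored standard
uncertainty is U/k.

The only finite-dof entry is KRISS in CCQM-K45, whose coverage factor of
2.45 corresponds to six effective degrees of freedom.  The two half-life
determinations published by the same 1965 study are labelled Fl65a/Fl65b to
keep labels unique.
"""

from __future__ import annotations

import math

from .data import KCStudy, MeasurementResult

__all__ = ["fixture", "FIXTURE_NAMES", "p3krbin_result"]

_INF = math.inf


def _study(name, unit, rows):
    return KCStudy(
        name,
        unit,
        tuple(
            MeasurementResult(lab, x, u, dof, inc) for lab, x, u, dof, inc in rows
        ),
    )


def _k45():
    # (lab, value, U, k); KRISS's k=2.45 corresponds to nu=6.
    raw = [
        ("KRISS", 226.26, 1.94, 2.45, 6.0),
        ("LGC", 224.6, 3.0, 2.0, _INF),
        ("LNE", 230.42, 5.97, 2.0, _INF),
        ("PTB", 227.0, 1.4, 2.0, _INF),
        ("UME", 209.8, 7.6, 2.0, _INF),
    ]
    rows = [
        (lab, x, U / k, dof, lab != "UME") for lab, x, U, k, dof in raw
    ]
    return _study("CCQM-K45", "mg/kg", rows)


def _k145_zn():
    raw = [
        ("EXHM", 420.6, 11.5, False),
        ("INRAP", 429.71, 9.48, False),
        ("UNIIM", 436.0, 9.0, False),
        ("LATU", 453.0, 5.6, True),
        ("INACAL", 453.1, 8.8, True),
        ("GLHK", 453.6, 7.7, True),
        ("NMIA", 454.1, 4.2, True),
        ("NIM", 454.5, 5.5, True),
        ("KRISS", 454.5, 6.7, True),
        ("LGC", 454.5, 3.9, True),
        ("NMISA", 454.5, 6.1, True),
        ("JSI", 455.0, 14.0, True),
        ("NIST", 456.2, 2.0, True),
        ("UME", 457.0, 4.0, True),
        ("HSA", 459.0, 7.1, True),
        ("PTB", 459.4, 1.7, True),
        ("RISE", 460.5, 3.2, True),
        ("SYKE", 460.9, 11.5, True),
        ("INMC", 461.0, 6.5, True),
        ("NRC", 462.0, 5.0, True),
        ("NIMT", 462.0, 13.2, True),
        ("NMIJ", 462.0, 3.0, True),
        ("KEBS", 474.22, 16.46, False),
        ("INRIM", 491.7, 10.0, False),
        ("VNIIFTRI", 524.0, 16.0, False),
    ]
    rows = [(lab, x, u, _INF, inc) for lab, x, u, inc in raw]
    return _study("CCQM-K145 (Zn)", "mg/kg", rows)


def _k145_ni():
    raw = [
        ("UNIIM", 0.147, 0.016, False),
        ("NMISA", 0.902, 0.038, False),
        ("EXHM", 1.017, 0.05, False),
        ("NIMT", 1.65, 0.06, False),
        ("JSI", 1.93, 0.11, True),
        ("INMC", 1.94, 0.06387, True),
        ("GLHK", 1.942, 0.092, True),
        ("LNE", 1.958, 0.075, True),
        ("VNIIFTRI", 1.96, 0.09, False),
        ("NIST", 1.984, 0.020, True),
        ("KRISS", 1.993, 0.033, True),
        ("INACAL", 2.01, 0.06, True),
        ("NMIA", 2.02, 0.05, True),
        ("NIM", 2.022, 0.023, True),
        ("NMIJ", 2.05, 0.02, True),
        ("RISE", 2.055, 0.052, True),
        ("NRC", 2.07, 0.05, True),
        ("PTB", 2.077, 0.035, True),
        ("LATU", 2.08, 0.059, True),
        ("LGC", 2.131, 0.042, True),
        ("UME", 2.15, 0.03, True),
        ("HSA", 2.18, 0.08, True),
        ("KEBS", 4.63, 0.94, False),
    ]
    rows = [(lab, x, u, _INF, inc) for lab, x, u, inc in raw]
    return _study("CCQM-K145 (Ni)", "mg/kg", rows)


def _k88():
    # u = U/2 throughout; final report included only the five ID-MS labs.
    raw = [
        ("INMETRO", 179.0, 4.0, False),
        ("VNIIM", 194.2, 10.0, False),
        ("NIM", 195.8, 2.6, True),
        ("NMIJ", 196.7, 1.52, True),
        ("KRISS", 197.2, 2.0, True),
        ("PTB", 197.9, 1.9, True),
        ("BAM", 198.29, 0.5, True),
        ("INTI", 199.0, 4.0, False),
        ("NIST", 199.43, 0.7, False),
        ("NRC", 202.4, 18.6, False),
    ]
    rows = [(lab, x, U / 2.0, _INF, inc) for lab, x, U, inc in raw]
    return _study("CCQM-K88", "mg/kg", rows)


def _k30_1():
    raw = [
        ("HSA", 12.3, 0.25),
        ("NMIA", 12.14, 0.12),
        ("LGC", 12.12, 0.155),
        ("NMISA", 12.08, 0.16),
        ("INMETRO", 11.8, 0.14),
        ("CMQ", 12.31, 0.06),
        ("INDECOPI", 12.16, 0.3),
        ("UME", 11.88, 0.32),
        ("EXHM", 11.424, 0.153),
        ("IJS", 10.45, 0.13),
    ]
    rows = [(lab, x, u, _INF, True) for lab, x, u in raw]
    return _study("CCQM-K30.1", "ng/g", rows)


def _zn65():
    raw = [
        ("ANSTO", 29610.0, 100.0, True),
        ("ASMW", 29480.0, 130.0, True),
        ("NIST", 29840.0, 190.0, True),
        ("BARC", 29130.0, 310.0, True),
        ("BEV", 29670.0, 330.0, False),
        ("CMI-IIR", 29850.0, 170.0, True),
        ("CNEA", 30030.0, 130.0, True),
        ("ENEA", 29660.0, 120.0, False),
        ("IFIN-HH", 29550.0, 150.0, True),
        ("IRA", 29720.0, 140.0, True),
        ("IRMM", 29661.0, 68.0, True),
        ("KRISS", 29780.0, 130.0, True),
        ("LNE-LNHB", 29810.0, 130.0, True),
        ("LNMRI/IRD", 30040.0, 160.0, True),
        ("MKEH", 29590.0, 120.0, True),
        ("NMIJ", 29700.0, 150.0, True),
        ("NMISA", 29870.0, 110.0, True),
        ("NPL", 29990.0, 110.0, True),
        ("PTB", 29710.0, 130.0, True),
        ("SMU", 29200.0, 670.0, False),
        ("VNIIM", 29727.0, 87.0, True),
    ]
    rows = [(lab, x, u, _INF, inc) for lab, x, u, inc in raw]
    return _study("BIPM.RI(II)-K1.Zn-65 + CCRI(II)-K2.Zn-65", "kBq", rows)


def p3krbin_result() -> MeasurementResult:
    """The 1993 P3KRBiN equivalent-activity result set aside from the Zn-65 KCRV."""
    return MeasurementResult("P3KRBiN", 28540.0, 89.0, _INF, True)


def _sr90():
    raw = [
        ("WT55", 10120.0, 150.0),
        ("An58", 10700.0, 580.0),
        ("Fl65a", 10230.0, 150.0),
        ("Fl65b", 10410.0, 330.0),
        ("Ho77", 10636.0, 88.0),
        ("La78", 10282.0, 12.0),
        ("Ra83", 10588.0, 91.0),
        ("Ko89", 10665.0, 37.0),
        ("Ma94", 10561.0, 14.0),
        ("WL96", 10495.0, 4.0),
        ("Sc04", 10557.0, 11.0),
    ]
    rows = [(lab, x, u, _INF, True) for lab, x, u in raw]
    return _study("Sr-90 half-life", "d", rows)


def _ccem():
    raw = [
        ("KRISS", 0.9143, 0.0104),
        ("LNE", 0.9157, 0.0018),
        ("NIST", 0.9184, 0.0064),
        ("NPL", 0.9167, 0.0060),
        ("PTB", 0.9153, 0.0031),
        ("VNIIFTRI", 0.9160, 0.0079),
        ("NIM", 0.8360, 0.0072),
        ("NRC", 0.9375, 0.0130),
    ]
    rows = [(lab, x, u, _INF, True) for lab, x, u in raw]
    return _study("CCEM.RF-K25.W (PTB-1, 36 GHz)", "", rows)


_BUILDERS = {
    "K45": _k45,
    "K145_Zn": _k145_zn,
    "K145_Ni": _k145_ni,
    "K88": _k88,
    "K30_1": _k30_1,
    "Zn65": _zn65,
    "Sr90": _sr90,
    "CCEM_RF_K25W": _ccem,
}

FIXTURE_NAMES = tuple(_BUILDERS)


def fixture(name: str) -> KCStudy:
    """Return one of the packaged datasets by short name.

    Valid names: K45, K145_Zn, K145_Ni, K88, K30_1, Zn65, Sr90, CCEM_RF_K25W.
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return builder()
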