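"""Shared fixtures: small hand-built wordlists and the heavier preset pipelines.

The preset pipelines (parameter recovery, coupled stability×iconicity, null
calibration) are expensive enough that they are computed once per session and
shared between the module tests and the acceptance checks.
"""

from __future__ import annotations

import pytest

import phonostab as ps
from phonostab.simulate import iconicity_counterpart


def make_wordlist(rows):
    """Build a Wordlist from (language, concept, ipa) triples."""
    forms = [
        ps.WordForm(
            language_id=lang,
            concept_id=concept,
            form=ipa.replace(" ", ""),
            segments=ps.segment_ipa(ipa),
        )
        for lang, concept, ipa in rows
    ]
    return ps.Wordlist(forms)


@pytest.fixture(scope="session")
def toy_wordlist():
    """Three languages, two concepts, with one regular correspondence k:k."""
    return make_wordlist(
        [
            ("A", "eye", "kala"),
            ("B", "eye", "kola"),
            ("C", "eye", "kalu"),
            ("A", "sun", "miki"),
            ("B", "sun", "meki"),
            ("C", "sun", "miku"),
        ]
    )


@pytest.fixture(scope="session")
def recovery_run():
    """Full stability pipeline on the parameter-recovery preset."""
    cfg = ps.default_presets()["recovery"]
    wl, truth = ps.simulate(cfg)
    sim = ps.estimate_pmi(wl)
    sets = ps.cluster_homologues(wl, sim)
    sst, pairs = ps.compute_sst(wl, sets, sim)
    return {
        "config": cfg,
        "wordlist": wl,
        "truth": truth,
        "sim": sim,
        "sets": sets,
        "sst": sst,
        "pairs": pairs,
    }


@pytest.fixture(scope="session")
def coupled_run():
    """Two-sample coupled experiment: SSt on the tree sample, Ico on the
    independent-language counterpart, joined into the combined table."""
    cfg = ps.default_presets()["coupled"]
    wl, truth = ps.simulate(cfg)
    sim = ps.estimate_pmi(wl)
    sets = ps.cluster_homologues(wl, sim)
    sst, _ = ps.compute_sst(wl, sets, sim)
    wl_ico, truth_ico = ps.simulate(iconicity_counterpart(cfg))
    ico = ps.build_iconicity_table(wl_ico, n_draws=4000, seed=202, prefilter=True)
    combined = ps.combine(ico, sst)
    return {
        "config": cfg,
        "sst": sst,
        "ico": ico,
        "truth": truth,
        "truth_ico": truth_ico,
        "combined": combined,
    }


@pytest.fixture(scope="session")
def null_ico_run():
    """Iconicity table under the no-iconicity null (unrelated languages)."""
    wl, _ = ps.simulate(ps.default_presets()["null"])
    return ps.build_iconicity_table(wl, n_draws=4000, seed=101, prefilter=True)
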