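import pytest

from famchar import binding_rules, domain_locator, residue_frame, synthetic_data


@pytest.fixture(scope="session")
def default_bundle():
    return synthetic_data.generate_family(synthetic_data.default_family_spec(seed=0))


@pytest.fixture(scope="session")
def default_pssm(default_bundle):
    return domain_locator.build_pssm(default_bundle.seed_alignment)


def classify_pipeline(bundle, pssm):
    """Full scan -> frame -> classify run over a bundle's proteins."""
    labels = {}
    for protein in bundle.proteins:
        hit = domain_locator.best_hit(domain_locator.scan_protein(protein, pssm))
        assert hit is not None, f"no domain hit in {protein.id}"
        domain = residue_frame.align_to_frame(hit, anchor_profile=pssm)
        labels[protein.id] = binding_rules.classify_binding(domain)
    return labels


@pytest.fixture(scope="session")
def pipeline_labels(default_bundle, default_pssm):
    return classify_pipeline(default_bundle, default_pssm)
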