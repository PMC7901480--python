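import pytest

from gisaq.standards import (DesignConstraints, assemble_internal_standard,
                             default_layout, design_specific_primers,
                             generate_spacer, generate_stuffer,
                             load_reference_standards)


@pytest.fixture(scope="session")
def reference_standards():
    """The five shipped 472-bp standards with detected layouts."""
    return load_reference_standards()


def build_standards(count=5, target_gc=0.46, seed=0, with_primers=True):
    layout = default_layout()
    variable = [s for s in layout.segments if s.length is not None]
    standards = []
    for k in range(count):
        stuffers = []
        for i, seg in enumerate(variable):
            sub_seed = seed * 1000 + k * 10 + i
            if seg.length < 20:
                stuffers.append(generate_spacer(seg.length, target_gc, sub_seed))
            else:
                stuffers.append(generate_stuffer(
                    DesignConstraints(target_length=seg.length,
                                      target_gc=target_gc), rng_seed=sub_seed))
        standards.append(assemble_internal_standard(layout, stuffers,
                                                    id=f"SYN{k + 1}"))
    if with_primers:
        for iss in standards:
            iss.specific_primers = design_specific_primers(
                iss, other_standards=standards, rng_seed=seed)
    return standards


@pytest.fixture(scope="session")
def designed_standards():
    """Five freshly designed synthetic standards with specific primers."""
    return build_standards(seed=0)
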