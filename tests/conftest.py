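import pytest

import radspatial as rs

WORKED_SENTENCES = [
    "There is hazy opacity of the lung consistent with hyaline membrane disease.",
    "A right PIC catheter terminates in the mid SVC.",
    "The UV line tip is high in the right atrium.",
    "ETT tube is 1 cm above the carina.",
    "A subtle area of increased signal adjacent to the left lateral ventricle "
    "at the level of corona radiata could be due to a small lacune.",
    "During the movement of the right foot, there is a small area of cortical "
    "BOLD activation adjacent to the area of edema.",
    "The lungs demonstrate hazy bilateral opacity of hyaline membrane disease.",
    "There are scattered T2 high signal intensity foci in the periventricular "
    "white matter and centrum semi-ovale consistent with microvascular angiopathy.",
    "A patchy area of consolidation is seen within the right lower lobe "
    "concerning for pneumonia.",
    "There is stable opacity in the right lower lobe as well as a retrocardiac "
    "opacity, these are likely related to atelactases versus pneumonia.",
]

# (sentence idx, trigger surface or None = any, entity surface, expected role)
WORKED_ROLES = [
    (0, "of", "opacity", "FIGURE"),
    (0, "of", "lung", "GROUND"),
    (0, "of", "consistent with", "HEDGE"),
    (0, "of", "hyaline membrane disease", "DIAGNOSIS"),
    (1, "in", "terminates", "POSITION_STATUS"),
    (2, "in", "high", "RELATIVE_POSITION"),
    (3, "above", "1 cm", "DISTANCE"),
    (4, None, "lacune", "REASON"),
    (5, None, "movement of the right foot", "ASSOCIATED_PROCESS"),
    (6, "demonstrate", "lungs", "GROUND"),
    (7, "in", "periventricular white matter", "GROUND"),
    (7, "in", "centrum semi-ovale", "GROUND"),
    (8, "within", "pneumonia", "DIAGNOSIS"),
    (9, "in", "atelactases", "DIAGNOSIS"),
]


@pytest.fixture(scope="session")
def entity_lexicon():
    return rs.default_entity_lexicon()


@pytest.fixture(scope="session")
def trigger_lexicon():
    return rs.default_trigger_lexicon()


@pytest.fixture(scope="session")
def worked_sentences():
    return [rs.tokenize(t, "paper", i) for i, t in enumerate(WORKED_SENTENCES)]


@pytest.fixture(scope="session")
def worked_result(worked_sentences):
    """Full pipeline (tag -> LFs -> label model) over the worked sentences."""
    return rs.weak_label(worked_sentences)
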