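"""Packaged fixtures: demo content pack, default intent registry and risk
lexicon, trial-simulation defaults, and a coverage conversation script.

Everything other modules need for a download-free end-to-end run ships
here. All dialog copy is original placeholder text; the *structure*
(module inventory, node palette, intent set sizes, funnel probabilities)
is what the fixtures model.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from ..channels import Script
from ..model import DialogGraph, parse_graph
from ..nlu import IntentRegistry, RiskLexicon
from .simulate import TrialSimConfig, simulate_trial

__all__ = [
    "TrialSimConfig",
    "build_demo_graph",
    "coverage_script",
    "default_intents",
    "default_risk_lexicon",
    "default_trial_config",
    "fixture_text",
    "simulate_trial",
]


def fixture_text(name: str) -> str:
    """Raw text of a packaged fixture file (e.g. ``demo_graph.yaml``)."""
    return (
        resources.files("korero").joinpath("data").joinpath(name).read_text("utf-8")
    )


@lru_cache(maxsize=None)
def _demo_graph_cached() -> DialogGraph:
    return parse_graph(fixture_text("demo_graph.yaml"))


def build_demo_graph() -> DialogGraph:
    """The demo content pack: a 25-module wellbeing chatbot.

    Onboarding block (intro with re-entry gate, onboarding, brief 0-10
    worry assessment, introductory information), 12 initial activity
    modules, 4 post-launch additions (tagged ``added_post_launch``), and
    the 5-module outro chain. Validates clean.
    """
    # deep copy so callers can mutate freely (tests seed defects)
    return _demo_graph_cached().model_copy(deep=True)


@lru_cache(maxsize=None)
def _intents_cached() -> IntentRegistry:
    return IntentRegistry.from_yaml(fixture_text("intents.yaml"))


def default_intents() -> IntentRegistry:
    """The default 40-intent registry (priority intents included)."""
    return _intents_cached().model_copy(deep=True)


@lru_cache(maxsize=None)
def _lexicon_cached() -> RiskLexicon:
    return RiskLexicon.from_yaml(fixture_text("risk_lexicon.yaml"))


def default_risk_lexicon() -> RiskLexicon:
    return _lexicon_cached().model_copy(deep=True)


def default_trial_config() -> TrialSimConfig:
    """Packaged trial-emulation parameters (see ``trial_default.yaml``)."""
    import yaml

    return TrialSimConfig.model_validate(
        yaml.safe_load(fixture_text("trial_default.yaml"))
    )


def coverage_script() -> Script:
    """Scripted conversation touching every node type of the demo pack."""
    return Script.from_yaml(fixture_text("coverage_script.yaml"))
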