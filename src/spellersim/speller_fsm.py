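"""Four-menu control paradigm of the messaging speller.

The asynchronous paradigm navigates four 7x7 menus:

* **NC** (No Control): 48 dummy cells and a central "IC" command; a
  resting state the user leaves with only ~1/49 chance per selection.
* **IC** (Intentional Control): ten commands (send/read per messaging
  service, Reply, Cancel, NC) among 39 dummies.
* **Spelling**: a 6x6 block of letters and digits, a column of seven
  predicted words, and a row with space, comma, two delete commands,
  "OK" and "IC".
* **Confirmation**: "Confirm"/"Back" guarding the destructive exits of
  the Spelling menu.

Selecting a "Send"/"Reply" command writes the fixed voice-command prefix
(e.g. ``Ok Google, send a WhatsApp to``) into the sentence buffer; the
user then spells receiver and message, separated by a single space, and
confirms, at which point the sentence is "spoken" (emitted as a string)
for the smartphone's virtual assistant.  A uniform-cost planner over
this state machine yields the minimum number of selections a task needs,
and a replanning user policy drives closed-loop simulations.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from importlib import resources

from .rcp_engine import MenuLayout, N_COLS, N_ROWS

DUMMY = "X"
MENU_NC = "NC"
MENU_IC = "IC"
MENU_SPELLING = "Spelling"
MENU_CONFIRMATION = "Confirmation"

#: canonical voice-command strings (English renderings; trailing space on
#: every prefix that is completed by spelling)
COMMAND_TEMPLATES: dict[str, str] = {
    "Send WA": "Ok Google, send a WhatsApp to ",
    "Send TG": "Ok Google, send a Telegram to ",
    "Send SMS": "Ok Google, send an SMS to ",
    "Send Mail": "Ok Google, send an e-mail to ",
    "Read WA": "Ok Google, read my WhatsApp messages",
    "Read TG": "Ok Google, read my Telegram messages",
    "Read SMS": "Ok Google, read my SMS messages",
    "Reply": "Ok Google, reply ",
    "Cancel": "Ok Google, cancel",
}
ROUTINE_WAIT = "Ok Google, wait a while"
ROUTINE_CANCEL = "Ok Google, routine cancel"

SEND_COMMANDS = ("Send WA", "Send TG", "Send SMS", "Send Mail")
READ_COMMANDS = ("Read WA", "Read TG", "Read SMS")

_SPELL_ROWS = ("ABCDEF", "GHIJKL", "MNOPQR", "STUVWX", "YZ0123", "456789")
_CONTROL_ROW = ("SPC", ",", "Del.", "Del. W", "OK", "IC")


# ---------------------------------------------------------------------------
# menu construction

def _layout(cells: dict[tuple[int, int], str]) -> MenuLayout:
    grid = tuple(
        tuple(cells.get((r, c), DUMMY) for c in range(N_COLS)) for r in range(N_ROWS)
    )
    mask = tuple(
        tuple((r, c) not in cells for c in range(N_COLS)) for r in range(N_ROWS)
    )
    return MenuLayout(grid, mask)


@dataclass(frozen=True)
class MenuCatalog:
    nc: MenuLayout
    ic: MenuLayout
    spelling: MenuLayout
    confirmation: MenuLayout

    def layout(self, menu: str) -> MenuLayout:
        return {MENU_NC: self.nc, MENU_IC: self.ic,
                MENU_SPELLING: self.spelling, MENU_CONFIRMATION: self.confirmation}[menu]


def build_menu_catalog() -> MenuCatalog:
    """The four menus.  Exact cell positions inside a menu are a free
    layout choice (they do not change any selection count)."""
    nc = _layout({(3, 3): "IC"})
    ic_cells = {}
    for c, cmd in enumerate(SEND_COMMANDS):
        ic_cells[(1, c + 1)] = cmd
    for c, cmd in enumerate(READ_COMMANDS):
        ic_cells[(3, c + 2)] = cmd
    for c, cmd in enumerate(("Reply", "Cancel", "NC")):
        ic_cells[(5, c + 2)] = cmd
    ic = _layout(ic_cells)

    spell_cells: dict[tuple[int, int], str] = {}
    for r, row in enumerate(_SPELL_ROWS):
        for c, ch in enumerate(row):
            spell_cells[(r, c)] = ch
    for r in range(N_ROWS):
        spell_cells[(r, 6)] = f"PRED{r + 1}"
    for c, cmd in enumerate(_CONTROL_ROW):
        spell_cells[(6, c)] = cmd
    spelling = _layout(spell_cells)

    confirmation = _layout({(3, 2): "Confirm", (3, 4): "Back"})
    return MenuCatalog(nc, ic, spelling, confirmation)


# ---------------------------------------------------------------------------
# word-prediction corpus

class WordCorpus:
    """Frequency table backing the seven prediction slots.

    ``predict(prefix)`` returns the highest-frequency words having the
    partial word as a (case-insensitive) prefix, frequency-descending with
    alphabetical tie-break; an empty partial word yields the globally most
    frequent words.
    """

    def __init__(self, entries) -> None:
        items = [(str(w), int(c)) for w, c in entries]
        if not items:
            raise ValueError("corpus must be nonempty")
        self._entries = sorted(items, key=lambda wc: (-wc[1], wc[0].lower()))

    def __len__(self) -> int:
        return len(self._entries)

    def predict(self, partial_word: str, n: int = 7) -> list[str]:
        p = partial_word.upper()
        return [w for w, _ in self._entries if w.upper().startswith(p)][:n]


def load_corpus(path) -> WordCorpus:
    """Read a UTF-8 ``word<TAB>count`` file."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            word, count = line.split()
            entries.append((word, int(count)))
    return WordCorpus(entries)


def packaged_corpus() -> WordCorpus:
    """The corpus fixture shipped with the package (guarantees the study's
    stated prediction availabilities for the default tasks)."""
    text = resources.files("spellersim").joinpath("data/prediction_corpus.txt").read_text("utf-8")
    entries = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            word, count = line.split()
            entries.append((word, int(count)))
    return WordCorpus(entries)


def predict_words(corpus: WordCorpus, partial_word: str, n: int = 7) -> list[str]:
    """The up-to-``n`` words offered in the prediction column."""
    return corpus.predict(partial_word, n)


# ---------------------------------------------------------------------------
# speller state and selection semantics

@dataclass(frozen=True)
class SpellerState:
    menu: str = MENU_NC
    sentence: str = ""
    prefix_len: int = 0                 # chars of sentence not spelled by the user
    pending: str = "none"               # "none" | "ok" | "ic"
    transcript: tuple[str, ...] = ()    # emitted voice commands, in order

    def __post_init__(self) -> None:
        if (self.pending != "none") != (self.menu == MENU_CONFIRMATION):
            raise ValueError("pending is set iff the menu is Confirmation")
        if self.menu == MENU_NC and self.sentence:
            raise ValueError("sentence must be empty in the NC menu")

    @property
    def spelled(self) -> str:
        """User-spelled portion of the sentence (prefix excluded)."""
        return self.sentence[self.prefix_len:]

    @property
    def partial_word(self) -> str:
        """Characters after the last space, i.e. the word being typed."""
        return self.spelled.rsplit(" ", 1)[-1]


@dataclass
class Effects:
    spoken: tuple[str, ...] = ()
    menu_changed: bool = False
    buffer_delta: int = 0   # change in spelled length


class Speller:
    """Selection semantics of the four menus (pure state transitions)."""

    def __init__(self, catalog: MenuCatalog | None = None,
                 corpus: WordCorpus | None = None,
                 emulate_routines: bool = False) -> None:
        self.catalog = catalog or build_menu_catalog()
        self.corpus = corpus or packaged_corpus()
        self.emulate_routines = emulate_routines

    def initial_state(self) -> SpellerState:
        return SpellerState()

    def predictions(self, state: SpellerState) -> list[str]:
        return self.corpus.predict(state.partial_word)

    def apply_selection(self, state: SpellerState, item: str) -> tuple[SpellerState, Effects]:
        """Apply one decided item; returns the new state and its effects.

        ``item`` must belong to the current menu's layout (dummies
        included).  Dummies, empty prediction slots, and deletes on an
        empty buffer are documented no-ops.
        """
        layout = self.catalog.layout(state.menu)
        if layout.find(item) is None:
            # not a command of this menu: either one of its dummy cells
            # (no effect) or a foreign item (error)
            in_grid = any(item.upper() == cell.upper()
                          for row in layout.grid for cell in row)
            if not in_grid:
                raise ValueError(f"item {item!r} is not in the {state.menu} menu")
            return state, Effects()
        handler = {
            MENU_NC: self._apply_nc, MENU_IC: self._apply_ic,
            MENU_SPELLING: self._apply_spelling,
            MENU_CONFIRMATION: self._apply_confirmation,
        }[state.menu]
        return handler(state, item)

    def apply_position(self, state: SpellerState,
                       position: tuple[int, int]) -> tuple[SpellerState, Effects]:
        item = self.catalog.layout(state.menu).item_at(position)
        return self.apply_selection(state, item)

    # -- per-menu handlers -------------------------------------------------

    def _apply_nc(self, state, item):
        if item == "IC":
            return replace(state, menu=MENU_IC), Effects(menu_changed=True)
        return state, Effects()

    def _apply_ic(self, state, item):
        if item in SEND_COMMANDS:
            prefix = COMMAND_TEMPLATES[item]
            new = replace(state, menu=MENU_SPELLING, sentence=prefix,
                          prefix_len=len(prefix))
            return new, Effects(menu_changed=True)
        if item in READ_COMMANDS:
            spoken = COMMAND_TEMPLATES[item]
            new = replace(state, menu=MENU_NC, sentence="", prefix_len=0,
                          transcript=state.transcript + (spoken,))
            return new, Effects(spoken=(spoken,), menu_changed=True)
        if item == "Reply":
            prefix = COMMAND_TEMPLATES["Reply"]
            spoken = (ROUTINE_WAIT,) if self.emulate_routines else ()
            new = replace(state, menu=MENU_SPELLING, sentence=prefix,
                          prefix_len=len(prefix),
                          transcript=state.transcript + spoken)
            return new, Effects(spoken=spoken, menu_changed=True)
        if item == "Cancel":
            spoken = (COMMAND_TEMPLATES["Cancel"],)
            if self.emulate_routines:
                spoken = spoken + (ROUTINE_CANCEL,)
            new = replace(state, menu=MENU_NC, sentence="", prefix_len=0,
                          transcript=state.transcript + spoken)
            return new, Effects(spoken=spoken, menu_changed=True)
        if item == "NC":
            return replace(state, menu=MENU_NC, sentence="", prefix_len=0), \
                Effects(menu_changed=True)
        raise ValueError(f"unhandled IC item {item!r}")

    def _apply_spelling(self, state, item):
        spelled = state.spelled
        if item == "OK":
            return replace(state, menu=MENU_CONFIRMATION, pending="ok"), \
                Effects(menu_changed=True)
        if item == "IC":
            return replace(state, menu=MENU_CONFIRMATION, pending="ic"), \
                Effects(menu_changed=True)
        if item == "Del.":
            if not spelled:
                return state, Effects()
            new_spelled = spelled[:-1]
        elif item == "Del. W":
            if not spelled:
                return state, Effects()
            trimmed = spelled.rstrip(" ")
            if " " in trimmed:
                new_spelled = trimmed.rsplit(" ", 1)[0] + " "
            else:
                new_spelled = ""
        elif item.startswith("PRED"):
            preds = self.predictions(state)
            idx = int(item[4:]) - 1
            if idx >= len(preds):
                return state, Effects()   # empty slot: no effect
            base = spelled[: len(spelled) - len(state.partial_word)]
            new_spelled = base + preds[idx] + " "
        elif item == "SPC":
            new_spelled = spelled + " "
        elif item == ",":
            new_spelled = spelled + ","
        elif len(item) == 1:
            new_spelled = spelled + item
        else:
            raise ValueError(f"unhandled Spelling item {item!r}")
        new = replace(state, sentence=state.sentence[: state.prefix_len] + new_spelled)
        return new, Effects(buffer_delta=len(new_spelled) - len(spelled))

    def _apply_confirmation(self, state, item):
        if item == "Back":
            return replace(state, menu=MENU_SPELLING, pending="none"), \
                Effects(menu_changed=True)
        if item == "Confirm":
            if state.pending == "ok":
                spoken = state.sentence
                new = replace(state, menu=MENU_NC, sentence="", prefix_len=0,
                              pending="none",
                              transcript=state.transcript + (spoken,))
                return new, Effects(spoken=(spoken,), menu_changed=True)
            new = replace(state, menu=MENU_IC, sentence="", prefix_len=0,
                          pending="none")
            return new, Effects(menu_changed=True)
        raise ValueError(f"unhandled Confirmation item {item!r}")


# ---------------------------------------------------------------------------
# tasks

@dataclass(frozen=True)
class Stage:
    """One goal utterance of a task: an IC command and, for send/reply
    commands, the text to spell after its prefix."""

    command: str
    spelled: str | None = None

    def __post_init__(self) -> None:
        if self.command not in COMMAND_TEMPLATES:
            raise ValueError(f"unknown command {self.command!r}")
        if (self.spelled is None) != (self.command in READ_COMMANDS + ("Cancel",)):
            raise ValueError("spelled text required exactly for send/reply commands")


@dataclass(frozen=True)
class TaskSpec:
    task_id: int
    stages: tuple[Stage, ...]
    description: str = ""


TASK1_PAYLOAD = "Francisco experimento en la universidad"
TASK4_RECEIVER = "Ricardo"


def default_tasks(task3_response: str = "PASTA",
                  task4_message: str = "HOLA QUE TAL ESTAS HOY") -> dict[int, TaskSpec]:
    """The four messaging tasks of the study protocol.

    Task 3's reply and Task 4's e-mail body are free text in the protocol;
    the defaults here are fixed fixture strings so runs are deterministic.
    """
    return {
        1: TaskSpec(1, (Stage("Send WA", TASK1_PAYLOAD),),
                    "WhatsApp to Francisco: 'experimento en la universidad'"),
        2: TaskSpec(2, (Stage("Read SMS", None),), "check received SMS"),
        3: TaskSpec(3, (Stage("Read TG", None), Stage("Reply", task3_response)),
                    "read Telegram and reply"),
        4: TaskSpec(4, (Stage("Send Mail", f"{TASK4_RECEIVER} {task4_message}"),),
                    "free e-mail to a chosen contact"),
    }


def task4_fixed_part() -> TaskSpec:
    """Task 4 without its free message: send an e-mail and select the
    receiver (predicted after two typed characters)."""
    return TaskSpec(4, (Stage("Send Mail", TASK4_RECEIVER),), "task 4, fixed actions")


def _norm(text: str) -> str:
    return text.upper().rstrip(" ")


def stage_done(spoken: str, stage: Stage) -> bool:
    """Whether a spoken utterance completes the stage's goal."""
    template = COMMAND_TEMPLATES[stage.command]
    if stage.spelled is None:
        return spoken == template
    return _norm(spoken) == _norm(template + stage.spelled)


def completed_stages(transcript, task: TaskSpec) -> int:
    """Number of leading task stages already satisfied by the transcript."""
    idx = 0
    for spoken in transcript:
        if idx < len(task.stages) and stage_done(spoken, task.stages[idx]):
            idx += 1
    return idx


# ---------------------------------------------------------------------------
# uniform-cost planner

class PlanningError(RuntimeError):
    pass


def _candidate_items(speller: Speller, state: SpellerState, stage: Stage) -> list[str]:
    """Moves worth exploring from a state (sound for shortest paths: any
    omitted move either has no effect or creates a deviation that costs
    strictly more selections to undo)."""
    if state.menu == MENU_NC:
        return ["IC"]
    if state.menu == MENU_IC:
        return [stage.command]
    if state.menu == MENU_CONFIRMATION:
        return ["Confirm", "Back"]
    # Spelling menu
    if stage.spelled is None:
        return ["IC"]  # wrong menu for a read stage: escape
    template = COMMAND_TEMPLATES[stage.command]
    if state.sentence[: state.prefix_len] != template or state.prefix_len != len(template):
        return ["IC"]  # wrong command prefix: escape and reissue
    target = _norm(stage.spelled)
    sp = state.spelled.upper()
    if not (target + " ").startswith(sp):
        return ["Del.", "Del. W"]
    moves: list[str] = []
    if sp.rstrip(" ") == target:
        moves.append("OK")
        return moves
    next_char = (target + " ")[len(sp)]
    moves.append("SPC" if next_char == " " else next_char)
    base_len = len(sp) - len(state.partial_word)
    for i, word in enumerate(speller.predictions(state)):
        new_sp = sp[:base_len] + word.upper() + " "
        if len(new_sp) > len(sp) and (target + " ").startswith(new_sp):
            moves.append(f"PRED{i + 1}")
    return moves


def plan_minimum_actions(task: TaskSpec, speller: Speller | None = None,
                         start_state: SpellerState | None = None,
                         start_stage: int | None = None,
                         max_nodes: int = 200_000) -> list[str]:
    """Shortest selection sequence completing the task, by breadth-first
    search over the speller state machine (prediction slots included).

    Starts in the NC menu by default; arbitrary start states are allowed,
    which is how the simulated user replans after an erroneous selection.
    """
    speller = speller or Speller()
    state = start_state if start_state is not None else speller.initial_state()
    stage_idx = (completed_stages(state.transcript, task)
                 if start_stage is None else start_stage)
    if stage_idx >= len(task.stages):
        return []

    def key(st: SpellerState, idx: int):
        return (idx, st.menu, st.pending, st.sentence[: st.prefix_len],
                st.spelled.upper())

    start = (state, stage_idx)
    seen = {key(state, stage_idx)}
    queue: deque = deque([(start, [])])
    nodes = 0
    while queue:
        (st, idx), path = queue.popleft()
        nodes += 1
        if nodes > max_nodes:
            raise PlanningError("search budget exhausted; goal likely unreachable")
        for item in _candidate_items(speller, st, task.stages[idx]):
            new_st, eff = speller.apply_selection(st, item)
            new_idx = idx
            for spoken in eff.spoken:
                if new_idx < len(task.stages) and stage_done(spoken, task.stages[new_idx]):
                    new_idx += 1
            new_path = path + [item]
            if new_idx >= len(task.stages):
                return new_path
            k = key(new_st, new_idx)
            if k not in seen:
                seen.add(k)
                queue.append(((new_st, new_idx), new_path))
    raise PlanningError(f"task {task.task_id} is unreachable from the start state")


def simulated_user_policy(state: SpellerState, task: TaskSpec,
                          speller: Speller | None = None) -> str | None:
    """Next item an error-aware user would attend to.

    Replans from the current state: after a wrong character the plan leads
    through "Del.", after a wrong predicted word through "Del. W", and
    after an unintended menu change back along the navigation graph.
    Returns ``None`` when the task is already complete.
    """
    speller = speller or Speller()
    if completed_stages(state.transcript, task) >= len(task.stages):
        return None
    plan = plan_minimum_actions(task, speller, start_state=state)
    return plan[0] if plan else None


def write_transcript_log(records, path) -> None:
    """CSV selection log (step, menu, intended, decided, correct, buffer,
    spoken)."""
    import pandas as pd

    pd.DataFrame(records, columns=[
        "step", "menu", "intended_item", "decided_item", "correct",
        "buffer", "spoken",
    ]).to_csv(path, index=False)
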