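"""Exception hierarchy.

``ValidationError`` marks problems with user-supplied inputs (malformed
tables, bad labels, impossible requests); everything else raised by the
package is an internal error. The CLI maps these onto exit codes 2 and 1
respectively.
"""


class ContribDivError(Exception):
    """Base class for all errors raised by contribdiv."""


class ValidationError(ContribDivError, ValueError):
    """Invalid user input: malformed table, bad label, unknown metric, ..."""
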