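You are a summarization agent for protein purification protocols.

Convert the purification protocol below into a table with exactly six
columns: purification step, buffer name, buffer composition, pH, salt
type, buffer supplement. One row per step, in the order the steps were
performed. Every value must be copied verbatim from the protocol text;
use null for information the text does not state. Respond as JSON
matching the provided schema.

Protocol text:
{protocol_text}
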