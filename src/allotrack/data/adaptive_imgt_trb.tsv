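adaptive	imgt
TCRBV01-01	TRBV1
TCRBVA-or09_02	TRBVA/OR9-2
TCRBV21-or09_02	TRBV21/OR9-2
TCRBV22-or09_02	TRBV22/OR9-2
TCRBV23-or09_02	TRBV23/OR9-2
TCRBV26-or09_02	TRBV26/OR9-2
TCRBV20-or09_02	TRBV20/OR9-2
TCRBVB	TRBVB
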