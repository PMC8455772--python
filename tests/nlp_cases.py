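"""Crafted report sentences with expected parse results.

Shared between the unit tests and the acceptance suite.  Each case is
(text, expected status, expected distance_cm or None).
"""

from ettcascade.reports import EttStatus

P, A, U = EttStatus.PRESENT, EttStatus.ABSENT, EttStatus.UNCERTAIN

CASES = [
    # presence with distances
    ("ET tube tip is 4.2 cm above the carina.", P, 4.2),
    ("ETT terminates 3 cm above the carina.", P, 3.0),
    ("The endotracheal tube tip terminates 4.5 cm above the carina.", P, 4.5),
    ("ETT tip 35 mm above the carina.", P, 3.5),
    ("ETT tip is 2.3cm above the carina.", P, 2.3),
    ("Endotracheal tube tip terminates 6.0 cm above the carina.", P, 6.0),
    ("ETT is 50 mm from the carina.", P, 5.0),
    ("The ETT tip lies 4 cm above the carina, unchanged in position.", P, 4.0),
    ("ET tube ends 1.8 cm above the carina.", P, 1.8),
    ("ETT tip terminates 0.8 cm above the carina.", P, 0.8),
    ("ETT tip measured 42 mm above the carina.", P, 4.2),
    ("ETT tip approximately 4.2 cm above carina.", P, 4.2),
    ("ETT tip is 4.2 cm above the level of the carina.", P, 4.2),
    ("Endotracheal tube tip 4.6 cm from the carina.", P, 4.6),
    ("The ETT remains in place, tip 3.9 cm above the carina.", P, 3.9),
    ("ETT 2 cm below the carina, advancement recommended.", P, 2.0),
    # presence without a usable distance
    ("Endotracheal tube in standard position.", P, None),
    ("Endo-tracheal tube present.", P, None),
    ("Satisfactory position of the ET tube.", P, None),
    ("Interval placement of an endotracheal tube.", P, None),
    ("ETT tip at the carina.", P, None),
    ("Tracheostomy tube and ETT noted.", P, None),
    ("ETT tip 100 cm above the carina.", P, None),  # implausible value
    # absence: negation, removal, or simply no mention
    ("No endotracheal tube is seen.", A, None),
    ("The endotracheal tube has been removed.", A, None),
    ("Patient has been extubated.", A, None),
    ("Normal chest radiograph.", A, None),
    ("Nasogastric tube in place.", A, None),
    ("ETT has been removed.", A, None),
    ("Interval removal of the endotracheal tube.", A, None),
    ("No ET tube identified.", A, None),
    ("Lines and tubes removed.", A, None),
    ("There is no evidence of an endotracheal tube.", A, None),
    ("The patient is without an endotracheal tube.", A, None),
    ("Feeding tube courses below the diaphragm.", A, None),
    ("ETT absent.", A, None),
    ("Status post extubation; lungs clear.", A, None),
    ("Right internal jugular central venous catheter in place.", A, None),
    ("Nasogastric tube tip 5 cm below the diaphragm; no endotracheal tube.", A, None),
    ("Esophageal temperature probe noted; no ETT.", A, None),
    ("Endotracheal tube removed; previously 4 cm above the carina.", A, None),
    # conflicting statements
    ("Lines and tubes unchanged. ETT in place. No ETT seen.", U, None),
    ("ETT in place. No ETT seen.", U, None),
    ("Endotracheal tube removed. New ETT placed at the thoracic inlet.", U, None),
    ("ET tube well positioned. Recommend removal of the ETT.", U, None),
]
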