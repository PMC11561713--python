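((((((t0001:0.13479676255436776,(t0006:0.05164924887374171,t0043:0.05145125485169469):0.07911605508321348):0.03549440574021491,(t0009:0.007929181239722888,t0044:0.007435867298547583):0.1613191034107573):0.0034064776748289343,(t0020:0.0016314256507568405,t0035:0.0013614952244374418):0.1570282340181496):0.08336760778677678,(t0003:0.026354795243627105,t0019:0.02349486121113658):0.1832100905902213):0.0955102489802404,(((t0007:0.03444931385574531,t0008:0.03951698862884486):0.002020101352499225,t0046:0.034924077394025664):0.2917887502040489,t0040:0.3074212077415207):0.008012557355099821):0.6473147494937491,(((((t0002:0.19311960396777225,((t0027:0.03532428419436155,(t0030:0.033047646844096085,(t0031:0.01855062597306276,t0033:0.022189156790395473):0.012189452271018966):0.0027289262131024628):0.12491400162454504,t0049:0.16395212784317298):0.043116669696943874):0.14336174542982874,((t0012:0.030223034055576053,t0042:0.03554171329092597):0.16722777461861835,((t0018:0.1520931699323094,((t0025:0.07051309014316537,t0038:0.07660694603618835):0.04482500971892892,t0026:0.11690782239655773):0.055815770889397265):0.05187484004429363,t0037:0.22648019550077367):0.028980389100876122):0.10571715369271611):0.22491169672118963,(t0005:0.30808897460151546,(t0015:0.07338906157134667,t0029:0.06922259671285033):0.23572720259829077):0.22145268386226427):0.020207338044526024,t0010:0.6031961457358379):0.0378015653703912,(((((t0004:0.0,t0028:0.0):0.1585411684943718,t0032:0.17672318048911664):0.12890002887176372,((t0011:0.09138211002100881,((t0021:0.01642902106541877,t0036:0.01651379465396448):0.03385808845335023,t0048:0.05456307053567194):0.04372729914286603):0.1614514775993819,t0024:0.2490428590642705):0.020636397058147096):0.11385930367768027,(((((t0014:0.051860301636701696,t0039:0.0579280266047913):0.09193492937150305,t0045:0.14111055677307205):0.013214656609055107,t0016:0.17082179677179332):0.20305495952573352,(((t0017:0.14134638998975377,(t0023:0.10411878562606776,t0041:0.10430871966891378):0.00768376116753682):0.0657243206419615,t0047:0.19195781864038608):0.004167136154615032,t0034:0.19310703692554745):0.19703340409618345):0.05274884834268381,t0050:0.3749231957931651):0.010492563528409174):0.1864550305847263,(t0013:0.2130621985828857,t0022:0.2151706353516262):0.37302867366487735):0.04053754537852711):0.29397786320679753);
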