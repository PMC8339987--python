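# Surface-form lexicon used by the synthetic report generator.
# Seeded from the published per-type instance column and expanded with common
# Chinese radiology phrasing so that taggers cannot memorise one string per type.
schema_version: 1
entities:
  Mass:
    primary: [肿物, 肿块, 软组织密度肿块, 软组织肿块, 占位, 团块影, 实性肿块, 分叶状肿物]
    satellite: [小结节, 小结节影, 微小结节, 结节影, 磨玻璃小结节]
    negated: [结节, 肿块, 实性结节, 占位病变]
  LymphNode:
    positive: [肿大淋巴结, 多发肿大淋巴结, 肿大的淋巴结, 增大淋巴结, 多发增大淋巴结]
    negated: [肿大淋巴结, 增大淋巴结, 明显肿大淋巴结]
  Negation: [未见, 无, 未见明显, 不伴, 未见确切]
  Density: [磨玻璃密度, 实性密度, 混杂密度, 低密度, 磨玻璃样密度, 密度不均匀, 密度均匀]
  Enhancement: [强化明显, 明显强化, 轻度强化, 不均匀强化, 中度强化, 均匀强化, 无明显强化, 环形强化]
  Shape: [边缘见毛刺, 分叶状改变, 边缘光滑, 形态不规则, 边缘毛糙, 浅分叶, 边界清楚, 边缘欠光整, 可见短毛刺]
  Bronchus: [支气管狭窄, 支气管截断, 累及支气管, 支气管壁增厚, 支气管受侵, 支气管闭塞]
  Pleura:
    invasion: [胸膜凹陷, 累及脏层胸膜, 侵犯脏层胸膜, 胸膜牵拉凹陷, 邻近胸膜受累, 脏层胸膜受侵]
    nodule: [胸膜多发结节, 胸膜结节, 胸膜面多发结节影]
    negated: [胸膜增厚, 胸膜异常增厚]
  Vessel: [包绕左肺动脉, 侵犯肺动脉, 累及上腔静脉, 包绕主动脉, 血管受侵, 包绕右肺动脉干]
  VertebralBody: [椎体见骨质破坏, 椎体受侵, 侵犯邻近椎体, 椎体骨质破坏]
  Effusion:
    present: [少量胸腔积液, 胸腔积液, 心包积液, 少量心包积液, 双侧胸腔积液, 右侧胸腔积液, 左侧胸腔积液]
    negated: [胸腔积液, 心包积液, 胸腔及心包积液]
  PAOP: [肺组织不张, 阻塞性肺炎, 肺不张, 阻塞性肺不张, 节段性肺不张]
location:
  segments: [尖段, 前段, 后段, 背段, 基底段, 外侧段, 内侧段, 舌段]
  remainder: [余肺, 余两肺, 双肺其余肺野]
cues:
  see: [见, 可见, 内见, 内可见]
  see_again: [另见, 亦见, 另可见]
  size_lead: [大小约, 约, 大小, 较大约, 较大者约]
distractors:
  - 双侧胸廓对称
  - 心影形态大小正常
  - 气管居中
  - 双侧膈面光整
  - 肋骨骨质连续
  - 扫描野内甲状腺形态正常
  - 胸壁形态正常
  - 双肺纹理清晰
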